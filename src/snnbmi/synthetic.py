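"""Class-conditional synthetic stimulus-evoked spike recordings.

Real evoked recordings (multi-channel spike trains aligned to the offset of an
intracortical microstimulation pattern) are not publicly available, so this
module generates statistically matched surrogates.  The generative model is an
inhomogeneous Poisson "mother" process per stimulus class whose intensity is

    lambda_c(t) = count_bias[c] * ( shared(t) + bumps_c(t) )

where ``shared(t)`` is a decaying post-stimulus transient common to all
classes (the strong early response every stimulation pattern evokes) and
``bumps_c(t)`` is a set of elevated-rate intervals at class-specific times
(the late, timing-coded structure that distinguishes classes).  A fraction of
bump positions, controlled by ``overlap``, is common to all classes: classes
share some spike timings.  ``count_bias`` makes classes differ in expected
total spike count.  Each mother-process spike is routed to one of the
``n_channels`` recording channels uniformly at random (independent thinning),
so channels are statistically interchangeable with near-identical timing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassTemplateSet",
    "EvokedRecording",
    "make_class_templates",
    "generate_evoked_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

N_CLASSES = 4
N_CHANNELS = 15

# Electrical metadata of the stimulation patterns the classes stand for
# (train of biphasic pulses); carried for fidelity, no computational role.
ICMS_METADATA = {
    "n_pulses": 10,
    "amplitude_ua": 100,
    "phase_us": 100,
    "polarity": "cathodic-first",
    "rate_hz": 333,
}


@dataclass(frozen=True)
class ClassTemplateSet:
    """Per-class firing-rate templates for the evoked-recording generator.

    Attributes
    ----------
    psth : ndarray, shape (n_classes, window_ms)
        Class intensity in spikes/ms of the merged (mother) process, one value
        per 1 ms bin.
    shared_profile : ndarray, shape (window_ms,)
        Baseline transient common to all classes (before count bias).
    class_bins : list of ndarray
        The class-specific elevated-rate bin indices of each class (bump
        support); useful for inspecting what a decoder should learn.
    """

    psth: np.ndarray
    shared_profile: np.ndarray
    overlap: float
    count_bias: np.ndarray
    class_bins: list[np.ndarray]
    n_channels: int = N_CHANNELS

    def __post_init__(self):
        if self.psth.ndim != 2 or self.psth.shape[0] != self.n_classes:
            raise ValueError("psth must be (n_classes, window_ms)")
        if np.any(self.psth < 0) or not np.all(np.isfinite(self.psth)):
            raise ValueError("rates must be finite and non-negative")
        if self.shared_profile.shape != (self.window_ms,):
            raise ValueError("shared_profile length must equal window_ms")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if np.any(self.count_bias <= 0):
            raise ValueError("count_bias must be positive")

    @property
    def n_classes(self) -> int:
        return int(self.psth.shape[0])

    @property
    def window_ms(self) -> int:
        return int(self.psth.shape[1])

    def expected_count(self, class_id: int) -> float:
        """Expected merged spike count of a trial of ``class_id`` (1-based)."""
        return float(self.psth[class_id - 1].sum())


@dataclass(frozen=True)
class EvokedRecording:
    """One post-stimulus trial: per-channel spike times + true stimulus class.

    Spike times are in ms relative to stimulation offset, strictly increasing
    within each channel, all within ``[0, duration_ms)``.
    """

    stimulus_class: int
    events: list[np.ndarray]
    duration_ms: float
    icms: dict = field(default_factory=lambda: dict(ICMS_METADATA), repr=False, compare=False)

    def __post_init__(self):
        evs = [np.asarray(e, dtype=float) for e in self.events]
        for e in evs:
            if e.size and (e.min() < 0 or e.max() >= self.duration_ms):
                raise ValueError("spike times must lie in [0, duration_ms)")
            if e.size > 1 and np.any(np.diff(e) <= 0):
                raise ValueError("per-channel spike times must be strictly increasing")
        object.__setattr__(self, "events", evs)

    @property
    def n_channels(self) -> int:
        return len(self.events)

    def merged(self) -> np.ndarray:
        """All channels pooled into one sorted spike-time array (duplicates kept)."""
        if not self.events:
            return np.empty(0)
        return np.sort(np.concatenate(self.events))

    @property
    def n_spikes(self) -> int:
        return int(sum(e.size for e in self.events))


def make_class_templates(
    window_ms: int = 300,
    overlap: float = 0.5,
    count_bias=(1.0, 1.0, 1.0, 1.0),
    base_rate: float = 0.12,
    seed: int = 0,
    *,
    n_classes: int = N_CLASSES,
    n_channels: int = N_CHANNELS,
    n_bumps: int = 6,
    bump_width_ms: int = 10,
    bump_rate: float | None = None,
    bump_t_min_ms: int = 60,
    bump_t_max_ms: int | None = None,
    shared_tau_ms: float = 40.0,
    shared_peak_factor: float = 3.0,
    shared_floor_factor: float = 0.25,
) -> ClassTemplateSet:
    """Build the per-class intensity templates.

    Parameters
    ----------
    window_ms : int
        Length of the generated post-stimulus window; the decoder later uses
        only its first 256 ms, so the default 300 ms exercises windowing.
    overlap : float in [0, 1]
        Fraction of each class's elevated-rate intervals placed at positions
        common to all classes.  0 gives disjoint class features, 1 identical.
    count_bias : sequence of float > 0
        Per-class multiplicative factor on the whole intensity, hence on the
        expected total spike count.
    base_rate : float
        Scale (spikes/ms) of the shared transient; the shared profile is
        ``base_rate * (floor + peak * exp(-t/tau))``.
    bump_rate : float, optional
        Added intensity inside a class bump; defaults to ``4 * base_rate``.
    """
    count_bias = np.asarray(count_bias, dtype=float)
    if not np.all(np.isfinite(count_bias)) or np.any(count_bias <= 0):
        raise ValueError("count_bias must be finite and positive")
    for name, v in (("base_rate", base_rate), ("overlap", overlap)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    if window_ms < 1:
        raise ValueError("window_ms must be >= 1")
    if count_bias.shape != (n_classes,):
        raise ValueError(f"count_bias must have {n_classes} entries")
    if bump_rate is None:
        bump_rate = 4.0 * base_rate
    if bump_rate < 0 or not np.isfinite(bump_rate):
        raise ValueError("bump_rate must be finite and non-negative")

    rng = np.random.default_rng(seed)
    t = np.arange(window_ms, dtype=float)
    shared = base_rate * (shared_floor_factor + shared_peak_factor * np.exp(-t / shared_tau_ms))

    # Non-overlapping candidate slots for the bumps, placed after the shared
    # early transient (class information lives in the late structure) and
    # before ``bump_t_max_ms``; enough slots must exist for fully disjoint
    # class features at overlap=0.
    t_max = window_ms if bump_t_max_ms is None else min(bump_t_max_ms, window_ms)
    t_min = min(bump_t_min_ms, t_max)
    first_slot = -(-t_min // bump_width_ms)
    n_slots = t_max // bump_width_ms - first_slot
    n_shared = int(round(overlap * n_bumps))
    n_unique = n_bumps - n_shared
    if n_shared + n_classes * n_unique > n_slots:
        raise ValueError("window too short for the requested bump layout")
    slots = first_slot + rng.permutation(n_slots)
    shared_slots = slots[:n_shared]
    rest = slots[n_shared:]

    psth = np.empty((n_classes, window_ms))
    class_bins: list[np.ndarray] = []
    for c in range(n_classes):
        unique_slots = rest[c * n_unique : (c + 1) * n_unique]
        own = np.concatenate([shared_slots, unique_slots]).astype(int)
        bins = np.concatenate(
            [np.arange(s * bump_width_ms, (s + 1) * bump_width_ms) for s in own]
        ) if own.size else np.empty(0, dtype=int)
        bump = np.zeros(window_ms)
        bump[bins] = bump_rate
        psth[c] = count_bias[c] * (shared + bump)
        class_bins.append(np.sort(bins))

    return ClassTemplateSet(
        psth=psth,
        shared_profile=shared,
        overlap=float(overlap),
        count_bias=count_bias,
        class_bins=class_bins,
        n_channels=n_channels,
    )


def generate_evoked_trial(
    templates: ClassTemplateSet, class_id: int, seed: int | np.random.Generator
) -> EvokedRecording:
    """Draw one trial of ``class_id`` (1-based) from the template intensity.

    Spikes are sampled per 1 ms bin as Poisson counts with the bin's intensity,
    placed uniformly within the bin (piecewise-constant inhomogeneous Poisson
    process), then routed to channels uniformly at random.
    """
    if not 1 <= class_id <= templates.n_classes:
        raise ValueError(f"unknown class_id {class_id}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = templates.psth[class_id - 1]
    counts = rng.poisson(lam)
    n = int(counts.sum())
    bins = np.repeat(np.arange(templates.window_ms), counts)
    times = bins + rng.random(n)
    channels = rng.integers(0, templates.n_channels, size=n)
    events = []
    for ch in range(templates.n_channels):
        tt = np.unique(times[channels == ch])  # sort; drop measure-zero ties
        events.append(tt)
    return EvokedRecording(
        stimulus_class=class_id, events=events, duration_ms=float(templates.window_ms)
    )


def generate_dataset(
    templates: ClassTemplateSet,
    n_train_per_class: int = 40,
    n_test_per_class: int = 10,
    seed: int = 0,
) -> tuple[list[EvokedRecording], list[EvokedRecording]]:
    """Independent train and test collections, class-balanced by construction.

    Defaults follow the experimental session layout: 40 training repetitions
    of each of the 4 stimulation patterns (160 recordings) and 10 test
    repetitions of each (40 recordings).
    """
    if n_train_per_class < 1 or n_test_per_class < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    train = [
        generate_evoked_trial(templates, c, rng)
        for c in range(1, templates.n_classes + 1)
        for _ in range(n_train_per_class)
    ]
    test = [
        generate_evoked_trial(templates, c, rng)
        for c in range(1, templates.n_classes + 1)
        for _ in range(n_test_per_class)
    ]
    return train, test


# ---------------------------------------------------------------------------
# Dataset round-trip serialization: JSON-lines, one trial per line.
# ---------------------------------------------------------------------------

def save_dataset(recordings: list[EvokedRecording], path) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(recordings):
            obj = {
                "trial_id": i,
                "class": rec.stimulus_class,
                "duration_ms": rec.duration_ms,
                "channels": [e.tolist() for e in rec.events],
            }
            fh.write(json.dumps(obj) + "\n")


def load_dataset(path) -> list[EvokedRecording]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                EvokedRecording(
                    stimulus_class=int(obj["class"]),
                    events=[np.asarray(e, dtype=float) for e in obj["channels"]],
                    duration_ms=float(obj["duration_ms"]),
                )
            )
    return out
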