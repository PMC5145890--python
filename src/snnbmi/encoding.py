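"""Temporal-to-spatial transformation of evoked recordings.

The plastic network learns mean-rate patterns, but the recordings carry their
class information in precise post-stimulus spike *timing*.  The bridge is a
binary binning code: the 15 recording channels are merged into one spike
train, the first 256 ms are binned at 1 ms, and each bin maps to one input
line (synapse column) of the network.  Occupied bins (at least one spike)
drive their line with a 400 ms, 100 Hz Poisson train during the presentation;
empty bins drive nothing.  During training a teacher line per ensemble adds a
75 Hz Poisson train to the true-class ensemble and 25 Hz to the other three.

Conventions: bins are 0-based half-open intervals ``[i, i+1)`` ms; input line
index equals bin index, identically for every neuron.
"""

from __future__ import annotations

import numpy as np

from .events import EventStream
from .synthetic import EvokedRecording

__all__ = [
    "WINDOW_MS",
    "merge_channels",
    "bin_recording",
    "bins_to_input_trains",
    "make_teacher_trains",
    "encode_recording",
]

WINDOW_MS = 256
INPUT_RATE_HZ = 100.0
TEACHER_POS_HZ = 75.0
TEACHER_NEG_HZ = 25.0
PRESENTATION_MS = 400.0


def merge_channels(recording: EvokedRecording) -> np.ndarray:
    """Pool all channels into a single ascending spike-time array.

    Duplicate times (coincident spikes on different channels) are preserved.
    """
    return recording.merged()


def bin_recording(times, window_ms: int = WINDOW_MS, bin_ms: int = 1) -> np.ndarray:
    """Occupancy bit vector: bit *i* set iff >= 1 spike in ``[i*bin, (i+1)*bin)``.

    Spikes at or beyond ``window_ms`` are ignored.  Occupancy, not count: any
    number of spikes in a bin sets its bit once.
    """
    if window_ms % bin_ms != 0:
        raise ValueError("bin_ms must divide window_ms")
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("negative spike times")
    n_bins = window_ms // bin_ms
    bits = np.zeros(n_bins, dtype=bool)
    idx = np.floor_divide(times, bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    bits[idx] = True
    return bits


def _poisson_train(rate_hz: float, duration_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration_ms) by exponential gaps."""
    if rate_hz <= 0:
        return np.empty(0)
    rate_per_ms = rate_hz / 1000.0
    # draw enough inter-arrival gaps in one shot, top up if unlucky
    n_guess = int(rate_per_ms * duration_ms * 3 + 20)
    gaps = rng.exponential(1.0 / rate_per_ms, size=n_guess)
    t = np.cumsum(gaps)
    while t.size and t[-1] < duration_ms:
        extra = rng.exponential(1.0 / rate_per_ms, size=n_guess)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < duration_ms]


def bins_to_input_trains(
    binvec: np.ndarray,
    rate_hz: float = INPUT_RATE_HZ,
    duration_ms: float = PRESENTATION_MS,
    seed: int | np.random.Generator = 0,
) -> EventStream:
    """Independent Poisson trains on the lines whose bits are set.

    Line *i* carries a homogeneous Poisson train of ``rate_hz`` over
    ``[0, duration_ms)`` iff ``binvec[i]``; all other lines are silent.
    """
    if rate_hz < 0:
        raise ValueError("rate_hz must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lines = {}
    for i in np.flatnonzero(np.asarray(binvec, dtype=bool)):
        lines[int(i)] = _poisson_train(rate_hz, duration_ms, rng)
    return EventStream.from_lines(lines)


def make_teacher_trains(
    true_class: int,
    rate_pos_hz: float = TEACHER_POS_HZ,
    rate_neg_hz: float = TEACHER_NEG_HZ,
    duration_ms: float = PRESENTATION_MS,
    seed: int | np.random.Generator = 0,
    n_ensembles: int = 4,
) -> EventStream:
    """Teacher event streams: 75 Hz to the true-class ensemble, 25 Hz to the rest.

    ``true_class`` is 1-based; ensemble addresses in the returned stream are
    0-based (ensemble ``true_class - 1`` receives the positive rate).
    """
    if not 1 <= true_class <= n_ensembles:
        raise ValueError(f"unknown class {true_class}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lines = {}
    for e in range(n_ensembles):
        rate = rate_pos_hz if e == true_class - 1 else rate_neg_hz
        lines[e] = _poisson_train(rate, duration_ms, rng)
    return EventStream.from_lines(lines)


def encode_recording(
    recording: EvokedRecording,
    rate_hz: float = INPUT_RATE_HZ,
    duration_ms: float = PRESENTATION_MS,
    window_ms: int = WINDOW_MS,
    seed: int | np.random.Generator = 0,
) -> EventStream:
    """Full pipeline: merge channels -> occupancy bits -> Poisson input trains."""
    bits = bin_recording(merge_channels(recording), window_ms=window_ms)
    return bins_to_input_trains(bits, rate_hz=rate_hz, duration_ms=duration_ms, seed=seed)
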