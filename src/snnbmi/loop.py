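"""Closed-loop control: workspace, calibration field, encoder, sessions.

The workspace is a 38 x 38 cm square centered on the target.  It is split
into four axis-aligned quadrant regions, each associated with one stimulation
pattern (class); the calibration force of a region is a unit vector from the
region's centroid to the target, the four together approximating a radial
force field with a central equilibrium point.

One closed-loop step: the encoder maps the object's position to the stimulus
class of its region (encoder ON) or draws a class at random (encoder OFF); a
test recording of that class is drawn from the held-out pool; the trained
network decodes it into ensemble counts, the counts weight the calibration
forces, and the object moves by ``gain`` times a first-order low-pass of the
decoded force (an object with mass; the ``inertia`` coefficient sets the
filter, 0 giving memoryless kinematics), clipped to the workspace.  Trials
stop on entering the circular target region (``target_region`` rule) or after
a fixed number of steps (``max_steps`` rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import counts_to_force, decode_recording
from .network import Network
from .synthetic import EvokedRecording

__all__ = [
    "Workspace",
    "CalibrationField",
    "Trajectory",
    "build_workspace",
    "calibrate_field",
    "encode_position",
    "select_test_recording",
    "step_dynamics",
    "precompute_decoded_counts",
    "run_trial",
    "run_session",
    "save_session",
    "load_session",
]

N_REGIONS = 4


@dataclass(frozen=True)
class Workspace:
    """Square workspace centered on the target, with quadrant sensory regions.

    Region labels (1-based), relative to the target at the origin of the
    region geometry, use half-open boundaries (``x >= 0`` counts right,
    ``y >= 0`` counts up):

    ====== =============
    label  quadrant
    ====== =============
    1      x >= 0, y >= 0
    2      x <  0, y >= 0
    3      x <  0, y <  0
    4      x >= 0, y <  0
    ====== =============
    """

    side_cm: float = 38.0
    target: np.ndarray = field(default_factory=lambda: np.zeros(2))
    target_radius_cm: float = 3.6
    start_ring_frac: float = 0.8
    start_ring_phase_deg: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if self.side_cm <= 0 or self.target_radius_cm <= 0:
            raise ValueError("degenerate geometry")
        if not self.target_radius_cm < self.side_cm / 2:
            raise ValueError("target radius must be smaller than half the side")

    @property
    def half(self) -> float:
        return self.side_cm / 2.0

    @property
    def centroids(self) -> np.ndarray:
        """Quadrant centroids (4, 2), in region-label order."""
        q = self.side_cm / 4.0
        offs = np.array([[q, q], [-q, q], [-q, -q], [q, -q]])
        return self.target + offs

    @property
    def start_positions(self) -> np.ndarray:
        """Eight equispaced, equidistant start positions on a ring (8, 2).

        The default phase 0 places four starts on the region borders and four
        on the quadrant diagonals; a phase of 22.5 degrees would center all
        eight inside the regions.
        """
        r = self.start_ring_frac * self.half
        ang = np.deg2rad(np.arange(8) * 45.0 + self.start_ring_phase_deg)
        return self.target + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    def contains(self, pos) -> bool:
        d = np.asarray(pos, dtype=float) - self.target
        return bool(np.all(np.abs(d) <= self.half))

    def clip(self, pos) -> np.ndarray:
        d = np.asarray(pos, dtype=float) - self.target
        return self.target + np.clip(d, -self.half, self.half)

    def in_target_region(self, pos) -> bool:
        return bool(
            np.linalg.norm(np.asarray(pos, dtype=float) - self.target)
            <= self.target_radius_cm
        )


@dataclass(frozen=True)
class CalibrationField:
    """Four calibration force vectors, one per sensory region (4, 2)."""

    forces: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.forces, dtype=float)
        if f.shape != (N_REGIONS, 2):
            raise ValueError("need one 2-D force per region")
        object.__setattr__(self, "forces", f)


@dataclass
class Trajectory:
    """One closed-loop run.

    ``positions`` has ``steps_used + 1`` rows (start included); ``stimuli``,
    ``counts`` and ``forces`` have one row per step.
    """

    positions: np.ndarray
    stimuli: np.ndarray
    counts: np.ndarray
    forces: np.ndarray
    converged: bool
    steps_used: int
    mode: str
    start_index: int = -1


def build_workspace(
    side_cm: float = 38.0,
    target=(0.0, 0.0),
    target_radius_cm: float = 3.6,
    start_ring_frac: float = 0.8,
    start_ring_phase_deg: float = 0.0,
) -> Workspace:
    """Workspace with four quadrant regions and the 8 canonical start points."""
    return Workspace(
        side_cm=side_cm,
        target=np.asarray(target, dtype=float),
        target_radius_cm=target_radius_cm,
        start_ring_frac=start_ring_frac,
        start_ring_phase_deg=start_ring_phase_deg,
    )


def calibrate_field(workspace: Workspace, magnitude: float = 1.0) -> CalibrationField:
    """Force of region k: ``magnitude * unit(target - centroid_k)``."""
    vecs = workspace.target - workspace.centroids
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("a region centroid coincides with the target")
    return CalibrationField(forces=magnitude * vecs / norms[:, None])


def encode_position(pos, workspace: Workspace) -> int:
    """Stimulus class (1-based region label) of an in-workspace position."""
    pos = np.asarray(pos, dtype=float)
    if not workspace.contains(pos):
        raise ValueError("position outside workspace")
    dx, dy = pos - workspace.target
    if dx >= 0:
        return 1 if dy >= 0 else 4
    return 2 if dy >= 0 else 3


def _pool_by_class(test_pool: list[EvokedRecording]) -> dict[int, list[int]]:
    by = {}
    for i, rec in enumerate(test_pool):
        by.setdefault(rec.stimulus_class, []).append(i)
    return by


def select_test_recording(
    class_or_none,
    test_pool: list[EvokedRecording],
    mode: str = "on",
    seed: int | np.random.Generator = 0,
) -> EvokedRecording:
    """Draw a test recording: from the given class (ON) or the whole pool (OFF)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _select_index(class_or_none, _pool_by_class(test_pool), len(test_pool), mode, rng)
    return test_pool[idx]


def _select_index(class_or_none, by_class, n_pool, mode, rng) -> int:
    if mode == "on":
        pool = by_class.get(class_or_none, [])
        if not pool:
            raise ValueError(f"no test recordings for class {class_or_none}")
        return int(pool[rng.integers(len(pool))])
    if mode == "off":
        return int(rng.integers(n_pool))
    raise ValueError("mode must be 'on' or 'off'")


def step_dynamics(pos, force, gain_cm: float, workspace: Workspace | None = None) -> np.ndarray:
    """Overdamped kinematics: displace by ``gain_cm * force``, clip to workspace."""
    if gain_cm <= 0:
        raise ValueError("gain_cm must be positive")
    new = np.asarray(pos, dtype=float) + gain_cm * np.asarray(force, dtype=float)
    if workspace is not None:
        new = workspace.clip(new)
    return new


def precompute_decoded_counts(
    network: Network, test_pool: list[EvokedRecording], seed: int = 0
) -> np.ndarray:
    """Decode every pool recording once; cache of shape (n_pool, 4).

    Mirrors the experimental reuse of a fixed held-out pool: during a session
    a recording contributes the same decoded counts every time it is drawn.
    """
    counts = np.empty((len(test_pool), N_REGIONS), dtype=np.int64)
    for i, rec in enumerate(test_pool):
        counts[i] = decode_recording(network, rec, seed=seed + i)
    return counts


def run_trial(
    network: Network | None,
    workspace: Workspace,
    field: CalibrationField,
    test_pool: list[EvokedRecording],
    start_pos,
    mode: str = "on",
    stop_rule: str = "target_region",
    max_steps: int = 100,
    gain_cm: float = 1.0,
    seed: int = 0,
    normalize: bool = True,
    inertia: float = 0.5,
    counts_cache: np.ndarray | None = None,
    counts_fn=None,
    start_index: int = -1,
) -> Trajectory:
    """One closed-loop trial from ``start_pos``.

    Per step: encode the position (ON) or draw a random stimulus (OFF); select
    a test recording accordingly; decode it to ensemble counts (from
    ``counts_cache`` if given, via ``counts_fn(recording, stimulus)`` if
    given — used for stubbed decoders — else by simulating the network);
    convert counts to a force and displace the object.  Under the
    ``target_region`` rule the trial stops as soon as a position enters the
    target disc; under ``max_steps`` it always runs ``max_steps`` steps.

    ``inertia`` models the controlled object's mass as a first-order low-pass
    on the applied force: the effective force is
    ``(1 - inertia) * decoded + inertia * previous``.  Zero gives memoryless
    kinematics (each step independent).  The recorded ``forces`` are the raw
    decoded forces; the smoothing affects only the motion.
    """
    if stop_rule not in ("target_region", "max_steps"):
        raise ValueError("stop_rule must be 'target_region' or 'max_steps'")
    if not 0 <= inertia < 1:
        raise ValueError("inertia must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_class = _pool_by_class(test_pool) if test_pool else {}
    pos = workspace.clip(np.asarray(start_pos, dtype=float))
    positions = [pos]
    stimuli, all_counts, forces = [], [], []
    f_eff = np.zeros(2)   # object starts at rest
    converged = workspace.in_target_region(pos)

    for _ in range(max_steps):
        if stop_rule == "target_region" and converged:
            break
        stim = encode_position(pos, workspace) if mode == "on" else int(rng.integers(1, N_REGIONS + 1))
        if counts_fn is not None:
            rec_idx = -1
            rec = None
            if test_pool:
                rec_idx = _select_index(stim if mode == "on" else None, by_class, len(test_pool), mode, rng)
                rec = test_pool[rec_idx]
            counts = np.asarray(counts_fn(rec, stim))
        else:
            rec_idx = _select_index(stim if mode == "on" else None, by_class, len(test_pool), mode, rng)
            if counts_cache is not None:
                counts = counts_cache[rec_idx]
            else:
                counts = decode_recording(network, test_pool[rec_idx], seed=int(rng.integers(2**31)))
        force = counts_to_force(counts, field, normalize=normalize)
        f_eff = (1.0 - inertia) * force + inertia * f_eff
        pos = step_dynamics(pos, f_eff, gain_cm, workspace)
        positions.append(pos)
        stimuli.append(stim)
        all_counts.append(np.asarray(counts))
        forces.append(force)
        if workspace.in_target_region(pos):
            converged = True

    return Trajectory(
        positions=np.asarray(positions),
        stimuli=np.asarray(stimuli, dtype=int),
        counts=np.asarray(all_counts, dtype=float).reshape(len(stimuli), N_REGIONS),
        forces=np.asarray(forces, dtype=float).reshape(len(stimuli), 2),
        converged=bool(converged),
        steps_used=len(stimuli),
        mode=mode,
        start_index=start_index,
    )


def run_session(
    network: Network | None,
    workspace: Workspace,
    field: CalibrationField,
    test_pool: list[EvokedRecording],
    n_per_start: int = 100,
    mode: str = "on",
    stop_rule: str = "target_region",
    max_steps: int = 100,
    gain_cm: float = 1.0,
    seed: int = 0,
    normalize: bool = True,
    inertia: float = 0.5,
    cache: bool = True,
    counts_fn=None,
) -> list[Trajectory]:
    """``n_per_start`` trials from each of the 8 start positions.

    With ``cache`` (default) the test pool is decoded once up front and the
    per-step forces looked up, matching the reuse of a fixed held-out pool.
    Trials are independently seeded from the session seed.
    """
    ss = np.random.SeedSequence([int(seed), 31])
    counts_cache = None
    if cache and counts_fn is None and network is not None and test_pool:
        counts_cache = precompute_decoded_counts(
            network, test_pool, seed=int(ss.generate_state(1)[0] % (2**31))
        )
    starts = workspace.start_positions
    children = ss.spawn(len(starts) * n_per_start)
    out = []
    k = 0
    for si, start in enumerate(starts):
        for _ in range(n_per_start):
            out.append(
                run_trial(
                    network, workspace, field, test_pool, start,
                    mode=mode, stop_rule=stop_rule, max_steps=max_steps,
                    gain_cm=gain_cm,
                    seed=int(children[k].generate_state(1)[0] % (2**31)),
                    normalize=normalize, inertia=inertia,
                    counts_cache=counts_cache,
                    counts_fn=counts_fn, start_index=si,
                )
            )
            k += 1
    return out


# ---------------------------------------------------------------------------
# Session serialization: one delimited-text record per step.
# ---------------------------------------------------------------------------

_HEADER = "trial_id\tstart_idx\tmode\tstep\tx\ty\tstimulus\tc1\tc2\tc3\tc4\tfx\tfy\tconverged"


def save_session(trajectories: list[Trajectory], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        r = lambda v: repr(float(v))
        for tid, tr in enumerate(trajectories):
            # step 0 row carries the start position; stimulus/counts/force blank
            fh.write(
                f"{tid}\t{tr.start_index}\t{tr.mode}\t0\t{r(tr.positions[0, 0])}\t"
                f"{r(tr.positions[0, 1])}\t\t\t\t\t\t\t\t{int(tr.converged)}\n"
            )
            for s in range(tr.steps_used):
                c = tr.counts[s]
                fh.write(
                    f"{tid}\t{tr.start_index}\t{tr.mode}\t{s + 1}\t"
                    f"{r(tr.positions[s + 1, 0])}\t{r(tr.positions[s + 1, 1])}\t"
                    f"{tr.stimuli[s]}\t{r(c[0])}\t{r(c[1])}\t{r(c[2])}\t{r(c[3])}\t"
                    f"{r(tr.forces[s, 0])}\t{r(tr.forces[s, 1])}\t{int(tr.converged)}\n"
                )


def load_session(path) -> list[Trajectory]:
    rows: dict[int, list[list[str]]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.setdefault(int(parts[0]), []).append(parts)
    out = []
    for tid in sorted(rows):
        rr = sorted(rows[tid], key=lambda p: int(p[3]))
        positions = np.array([[float(p[4]), float(p[5])] for p in rr])
        steps = [p for p in rr if p[6] != ""]
        out.append(
            Trajectory(
                positions=positions,
                stimuli=np.array([int(p[6]) for p in steps], dtype=int),
                counts=np.array(
                    [[float(p[7]), float(p[8]), float(p[9]), float(p[10])] for p in steps]
                ).reshape(len(steps), N_REGIONS),
                forces=np.array([[float(p[11]), float(p[12])] for p in steps]).reshape(
                    len(steps), 2
                ),
                converged=bool(int(rr[0][13])),
                steps_used=len(steps),
                mode=rr[0][2],
                start_index=int(rr[0][1]),
            )
        )
    return out
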