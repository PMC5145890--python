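"""Integrate-and-fire network with bistable, calcium-gated plastic synapses.

This is a software emulation of a mixed-signal neuromorphic decoder substrate:
256 input lines fan into 252 linear-leak integrate-and-fire neurons, each
owning one plastic synapse per input line (synapse *i* of every neuron listens
to line *i*).  Synapses follow a spike-driven bistable plasticity rule: an
internal analog variable ``x`` jumps up or down on pre-synaptic spikes, gated
by the post-synaptic membrane value and a calcium trace (a low-pass filter of
the post-synaptic spike train), and drifts between spikes toward one of two
attractors (0 or ``x_max``) depending on which side of the bistability
threshold it sits.  The expressed synaptic weight is binary: ``j_high`` when
``x`` is above threshold, ``j_low`` otherwise.

The upper calcium bound on potentiation implements *stop-learning*: once a
neuron fires fast enough that its calcium exceeds the bound, no further
potentiation is possible.  This caps a neuron's total excitatory input,
creating heterosynaptic competition that normalizes the output across input
classes with different spike-count energy.

Neurons are grouped into four ensembles of 63; each ensemble has a dedicated
non-plastic teacher line.  Per-neuron fabrication mismatch is emulated as
seeded Gaussian jitter of the threshold and leak, which diversifies the
decision boundaries within an ensemble.

Simulation is clock-driven at fixed ``dt_ms`` (default 0.1 ms), with event
times snapped to the grid; synapse drift is applied lazily in closed form
between the events that touch a synapse, which is exact because drift never
crosses the bistability threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .events import EventStream

__all__ = [
    "NeuronParams",
    "NeuronState",
    "PlasticSynapse",
    "PlasticityParams",
    "NetworkConfig",
    "Network",
    "PresentationResult",
    "build_network",
    "step_neuron",
    "update_calcium",
    "on_pre_spike",
    "drift_synapse",
]


# ---------------------------------------------------------------------------
# Parameter / state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Linear-leak integrate-and-fire neuron constants (model units).

    ``v`` integrates synaptic drive against a constant leak and is floored at
    zero; crossing ``v_thresh`` emits a spike, resets to ``v_reset`` and opens
    a refractory window.  ``tau_ca``/``j_ca`` define the calcium trace used to
    gate plasticity.  ``mismatch_cv`` is the coefficient of variation of the
    per-neuron fabrication-mismatch jitter, applied to ``v_thresh``, ``leak``,
    the plasticity gates (``theta_v`` and the calcium windows) and the teacher
    weight when the network is built.
    """

    v_thresh: float = 1.0
    v_reset: float = 0.0
    leak: float = 0.025         # per ms
    refractory_ms: float = 2.0
    tau_ca: float = 20.0        # ms
    j_ca: float = 3.0
    mismatch_cv: float = 0.10

    def __post_init__(self):
        if not self.v_thresh > self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")
        if self.leak < 0 or self.refractory_ms < 0 or self.mismatch_cv < 0:
            raise ValueError("leak, refractory_ms and mismatch_cv must be >= 0")
        if not self.tau_ca > 0:
            raise ValueError("tau_ca must be positive")


@dataclass
class NeuronState:
    v: float = 0.0
    ca: float = 0.0
    refractory_remaining: float = 0.0
    spike_count: int = 0


@dataclass(frozen=True)
class PlasticityParams:
    """Bistable spike-driven plasticity constants.

    On a pre-synaptic spike, with post-synaptic membrane ``v`` and calcium
    ``ca``:

    * potentiate (``x += a_up``) if ``v > theta_v`` and
      ``theta_ca_up_low <= ca < theta_ca_up_high`` — the upper bound is the
      stop-learning gate;
    * depress (``x -= b_down``) if ``v <= theta_v`` and
      ``theta_ca_dn_low <= ca < theta_ca_dn_high``;
    * otherwise leave ``x`` unchanged.

    Between updates ``x`` drifts at ``drift_up``/``drift_dn`` per ms toward
    ``x_max`` or 0 depending on its side of ``theta_x``; the expressed binary
    efficacy is ``j_high`` iff ``x >= theta_x`` else ``j_low``.
    """

    a_up: float = 0.10
    b_down: float = 0.035
    theta_v: float = 0.40
    theta_ca_up_low: float = 1.9
    theta_ca_up_high: float = 3.4
    theta_ca_dn_low: float = 0.3
    theta_ca_dn_high: float = 2.4
    drift_up: float = 0.002     # per ms
    drift_dn: float = 0.002     # per ms
    theta_x: float = 0.5
    x_max: float = 1.0
    j_low: float = 0.0
    j_high: float = 0.006

    def __post_init__(self):
        if not 0 < self.theta_x < self.x_max:
            raise ValueError("need 0 < theta_x < x_max")
        if self.theta_ca_up_low >= self.theta_ca_up_high:
            raise ValueError("potentiation calcium window must be ordered")
        if self.theta_ca_dn_low >= self.theta_ca_dn_high:
            raise ValueError("depression calcium window must be ordered")
        for name in ("a_up", "b_down", "drift_up", "drift_dn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlasticSynapse:
    """One bistable synapse: analog variable ``x`` with binary efficacy."""

    x: float = 0.0

    def efficacy(self, params: PlasticityParams) -> float:
        return params.j_high if self.x >= params.theta_x else params.j_low


@dataclass(frozen=True)
class NetworkConfig:
    n_neurons: int = 252
    n_ensembles: int = 4
    ensemble_size: int = 63
    n_plastic_synapses_per_neuron: int = 256
    teacher_efficacy: float = 0.82
    dt_ms: float = 0.1
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    plasticity_params: PlasticityParams = field(default_factory=PlasticityParams)
    seed: int = 0
    x_init: str = "depressed"   # "depressed" | "uniform"

    def __post_init__(self):
        if self.n_ensembles * self.ensemble_size != self.n_neurons:
            raise ValueError("n_ensembles * ensemble_size must equal n_neurons")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.n_plastic_synapses_per_neuron < 1:
            raise ValueError("need at least one synapse per neuron")
        if self.x_init not in ("uniform", "depressed"):
            raise ValueError("x_init must be 'uniform' or 'depressed'")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["neuron_params"] = NeuronParams(**d["neuron_params"])
        d["plasticity_params"] = PlasticityParams(**d["plasticity_params"])
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Single-neuron / single-synapse reference operations
# ---------------------------------------------------------------------------

def step_neuron(
    state: NeuronState, input_value: float, dt_ms: float, params: NeuronParams
) -> tuple[NeuronState, bool]:
    """One clock step of the linear-leak integrate-and-fire update.

    Returns the new state and whether the neuron spiked this step.  No
    integration occurs while refractory; the membrane is floored at zero.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    s = replace(state)
    if s.refractory_remaining > 0:
        s.refractory_remaining = max(0.0, s.refractory_remaining - dt_ms)
        return s, False
    v = max(0.0, s.v - params.leak * dt_ms + input_value)
    if v >= params.v_thresh:
        s.v = params.v_reset
        s.refractory_remaining = params.refractory_ms
        s.spike_count += 1
        return s, True
    s.v = v
    return s, False


def update_calcium(
    state: NeuronState, spiked: bool, dt_ms: float, params: NeuronParams
) -> NeuronState:
    """Exponential calcium decay plus a fixed increment per output spike."""
    s = replace(state)
    s.ca = s.ca * float(np.exp(-dt_ms / params.tau_ca))
    if spiked:
        s.ca += params.j_ca
    return s


def on_pre_spike(
    synapse: PlasticSynapse, v_post: float, ca_post: float, params: PlasticityParams
) -> PlasticSynapse:
    """Apply the calcium-gated bistable update for one pre-synaptic spike."""
    x = synapse.x
    if v_post > params.theta_v and params.theta_ca_up_low <= ca_post < params.theta_ca_up_high:
        x = min(x + params.a_up, params.x_max)
    elif v_post <= params.theta_v and params.theta_ca_dn_low <= ca_post < params.theta_ca_dn_high:
        x = max(x - params.b_down, 0.0)
    return PlasticSynapse(x=x)


def drift_synapse(
    synapse: PlasticSynapse, dt_ms: float, params: PlasticityParams
) -> PlasticSynapse:
    """Drift ``x`` toward its attractor for an idle interval of ``dt_ms``.

    ``x == theta_x`` is a fixed point; drift never crosses the threshold, so
    this closed form is exact for any interval length.
    """
    x = synapse.x
    if x > params.theta_x:
        x = min(x + params.drift_up * dt_ms, params.x_max)
    elif x < params.theta_x:
        x = max(x - params.drift_dn * dt_ms, 0.0)
    return PlasticSynapse(x=x)


# ---------------------------------------------------------------------------
# Vectorized clock-driven simulation kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _drift_column(x, i, dt_ms, theta_x, x_max, drift_up, drift_dn):
    n = x.shape[0]
    for nn in range(n):
        xi = x[nn, i]
        if xi > theta_x:
            xi = xi + drift_up * dt_ms
            if xi > x_max:
                xi = x_max
        elif xi < theta_x:
            xi = xi - drift_dn * dt_ms
            if xi < 0.0:
                xi = 0.0
        x[nn, i] = xi


@njit(cache=True)
def _simulate(
    n_steps, dt,
    ev_step, ev_line,           # pre-sorted input events (grid step, line id)
    te_step, te_ens,            # teacher events (grid step, ensemble id)
    x,                          # (n_neurons, n_lines), modified in place
    theta_x, x_max, j_low, j_high,
    a_up, b_down, theta_v,
    ca_up_l, ca_up_h, ca_dn_l, ca_dn_h,   # per-neuron (mismatch-jittered)
    drift_up, drift_dn,
    plasticity_on,
    v_thresh, leak,             # per-neuron (mismatch-jittered)
    v_reset, refr_steps, ca_decay, j_ca,
    teacher_eff, ensemble_of,
):
    n = x.shape[0]
    m = x.shape[1]
    v = np.zeros(n)
    ca = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    drive = np.zeros(n)
    last_upd = np.zeros(m, dtype=np.int64)
    n_pot = 0
    n_dep = 0
    total_drive = 0.0

    cap = n * (n_steps // (refr_steps + 1) + 1)
    out_step = np.empty(cap, dtype=np.int64)
    out_neuron = np.empty(cap, dtype=np.int64)
    n_out = 0

    ei = 0
    ti = 0
    n_ev = ev_step.shape[0]
    n_te = te_step.shape[0]

    for s in range(n_steps):
        for nn in range(n):
            drive[nn] = 0.0
        # input events landing on this step
        while ei < n_ev and ev_step[ei] == s:
            i = ev_line[ei]
            if plasticity_on:
                _drift_column(x, i, (s - last_upd[i]) * dt,
                              theta_x, x_max, drift_up, drift_dn)
                last_upd[i] = s
            for nn in range(n):
                w = j_high if x[nn, i] >= theta_x else j_low
                drive[nn] += w
                total_drive += w
            if plasticity_on:
                for nn in range(n):
                    if v[nn] > theta_v[nn] and ca_up_l[nn] <= ca[nn] < ca_up_h[nn]:
                        xi = x[nn, i] + a_up
                        if xi > x_max:
                            xi = x_max
                        if xi > x[nn, i]:
                            n_pot += 1
                        x[nn, i] = xi
                    elif v[nn] <= theta_v[nn] and ca_dn_l[nn] <= ca[nn] < ca_dn_h[nn]:
                        xi = x[nn, i] - b_down
                        if xi < 0.0:
                            xi = 0.0
                        if xi < x[nn, i]:
                            n_dep += 1
                        x[nn, i] = xi
            ei += 1
        # teacher events (non-plastic, ensemble-targeted)
        while ti < n_te and te_step[ti] == s:
            e = te_ens[ti]
            for nn in range(n):
                if ensemble_of[nn] == e:
                    drive[nn] += teacher_eff[nn]
            ti += 1
        # membrane + calcium update
        for nn in range(n):
            ca[nn] *= ca_decay
            if refr[nn] > 0:
                refr[nn] -= 1
                continue
            vv = v[nn] - leak[nn] * dt + drive[nn]
            if vv < 0.0:
                vv = 0.0
            if vv >= v_thresh[nn]:
                counts[nn] += 1
                ca[nn] += j_ca
                vv = v_reset
                refr[nn] = refr_steps
                out_step[n_out] = s
                out_neuron[n_out] = nn
                n_out += 1
            v[nn] = vv

    if plasticity_on:
        for i in range(m):
            _drift_column(x, i, (n_steps - last_upd[i]) * dt,
                          theta_x, x_max, drift_up, drift_dn)

    return counts, n_pot, n_dep, total_drive, out_step[:n_out], out_neuron[:n_out]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class PresentationResult:
    """Outcome of one presentation window."""

    neuron_counts: np.ndarray          # per-neuron output spike counts
    ensemble_counts: np.ndarray        # per-ensemble sums (length n_ensembles)
    n_potentiation_events: int
    n_depression_events: int
    total_injected_drive: float        # sum of efficacies over delivered input events
    output: EventStream | None = None


class Network:
    """A built network: jittered neuron parameters plus the synapse matrix.

    Attributes
    ----------
    x : ndarray, shape (n_neurons, n_lines)
        Analog synaptic variables.
    v_thresh, leak : ndarray, shape (n_neurons,)
        Per-neuron constants after mismatch jitter.
    ensemble_of : ndarray
        Ensemble index of each neuron (``n // ensemble_size``).
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        np_ = config.neuron_params
        rng = np.random.default_rng(config.seed)
        cv = np_.mismatch_cv
        n = config.n_neurons
        jitter = lambda base: np.clip(
            base * (1.0 + cv * rng.standard_normal(n)), 0.05 * base if base > 0 else 0.0, None
        )
        # Device mismatch: every nominally identical analog sub-circuit gets its
        # own operating point — membrane threshold and leak, the plasticity
        # comparators (membrane gate, calcium windows; each window scaled by one
        # factor so its ordering is preserved), and the teacher synapse weight.
        # This per-neuron diversity is what lets an ensemble act as 63 weak
        # learners with different decision boundaries rather than 63 clones.
        self.v_thresh = jitter(np_.v_thresh)
        self.leak = jitter(np_.leak)
        pp0 = config.plasticity_params
        self.theta_v = jitter(pp0.theta_v)
        s_up = np.clip(1.0 + cv * rng.standard_normal(n), 0.05, None)
        s_dn = np.clip(1.0 + cv * rng.standard_normal(n), 0.05, None)
        self.ca_up_low = pp0.theta_ca_up_low * s_up
        self.ca_up_high = pp0.theta_ca_up_high * s_up
        self.ca_dn_low = pp0.theta_ca_dn_low * s_dn
        self.ca_dn_high = pp0.theta_ca_dn_high * s_dn
        self.teacher_eff = jitter(config.teacher_efficacy)
        m = config.n_plastic_synapses_per_neuron
        pp = config.plasticity_params
        if config.x_init == "uniform":
            self.x = rng.uniform(0.0, pp.x_max, size=(n, m))
        else:
            self.x = np.zeros((n, m))
        self.ensemble_of = (
            np.arange(n, dtype=np.int64) // config.ensemble_size
        )
        self.training_log: list[dict] = []

    # -- properties ----------------------------------------------------------

    @property
    def efficacy(self) -> np.ndarray:
        """Binary weight matrix expressed by the current ``x``."""
        pp = self.config.plasticity_params
        return np.where(self.x >= pp.theta_x, pp.j_high, pp.j_low)

    @property
    def potentiated(self) -> np.ndarray:
        return self.x >= self.config.plasticity_params.theta_x

    # -- simulation ----------------------------------------------------------

    def simulate_presentation(
        self,
        input_trains: EventStream,
        teacher_trains: EventStream | None,
        duration_ms: float,
        plasticity_on: bool,
        record_output: bool = False,
    ) -> PresentationResult:
        """Run one clock-driven presentation of ``duration_ms``.

        Each input event on line *i* injects the current efficacy of synapse
        *i* into every neuron; teacher events inject ``teacher_efficacy`` into
        their ensemble only.  Plasticity (jump on pre-spike + attractor drift)
        is applied when ``plasticity_on``.  Membrane/calcium state starts from
        rest; output spikes are counted within ``[0, duration_ms)``.  The
        dynamics are deterministic given the event streams.
        """
        if duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        cfg = self.config
        dt = cfg.dt_ms
        n_steps = int(round(duration_ms / dt))

        def grid(stream: EventStream | None, n_addr: int, what: str):
            if stream is None or len(stream) == 0:
                return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            if stream.times.min() < 0 or stream.times.max() >= duration_ms:
                raise ValueError(f"{what} events outside [0, duration_ms)")
            if stream.addresses.min() < 0 or stream.addresses.max() >= n_addr:
                raise ValueError(f"{what} address out of range")
            steps = np.minimum((stream.times / dt).astype(np.int64), n_steps - 1)
            order = np.argsort(steps, kind="stable")
            return steps[order], stream.addresses[order]

        ev_step, ev_line = grid(input_trains, cfg.n_plastic_synapses_per_neuron, "input")
        te_step, te_ens = grid(teacher_trains, cfg.n_ensembles, "teacher")

        np_, pp = cfg.neuron_params, cfg.plasticity_params
        counts, n_pot, n_dep, total_drive, out_step, out_neuron = _simulate(
            n_steps, dt, ev_step, ev_line, te_step, te_ens,
            self.x,
            pp.theta_x, pp.x_max, pp.j_low, pp.j_high,
            pp.a_up, pp.b_down, self.theta_v,
            self.ca_up_low, self.ca_up_high,
            self.ca_dn_low, self.ca_dn_high,
            pp.drift_up, pp.drift_dn,
            plasticity_on,
            self.v_thresh, self.leak,
            np_.v_reset, int(round(np_.refractory_ms / dt)),
            float(np.exp(-dt / np_.tau_ca)), np_.j_ca,
            self.teacher_eff, self.ensemble_of,
        )
        ens_counts = np.bincount(
            self.ensemble_of, weights=counts, minlength=cfg.n_ensembles
        ).astype(np.int64)
        output = None
        if record_output:
            output = EventStream(out_step * dt, out_neuron)
        return PresentationResult(
            neuron_counts=counts,
            ensemble_counts=ens_counts,
            n_potentiation_events=int(n_pot),
            n_depression_events=int(n_dep),
            total_injected_drive=float(total_drive),
            output=output,
        )

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Write a text checkpoint: config, x matrix, jittered constants."""
        obj = {
            "config": self.config.to_dict(),
            "config_hash": self.config.content_hash(),
            "x": self.x.tolist(),
        }
        for name in self._MISMATCH_ARRAYS:
            obj[name] = getattr(self, name).tolist()
        with open(path, "w") as fh:
            json.dump(obj, fh)

    _MISMATCH_ARRAYS = (
        "v_thresh", "leak", "theta_v",
        "ca_up_low", "ca_up_high", "ca_dn_low", "ca_dn_high", "teacher_eff",
    )

    @classmethod
    def load(cls, path) -> "Network":
        with open(path) as fh:
            obj = json.load(fh)
        config = NetworkConfig.from_dict(obj["config"])
        net = cls(config)
        net.x = np.asarray(obj["x"], dtype=float)
        for name in cls._MISMATCH_ARRAYS:
            setattr(net, name, np.asarray(obj[name], dtype=float))
        return net


def build_network(config: NetworkConfig) -> Network:
    """Construct a network per the configuration (seeded mismatch jitter)."""
    return Network(config)
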