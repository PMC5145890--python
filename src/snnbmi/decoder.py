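"""Ensemble spike-count decoding: training, classification, force readout.

The trained network turns an evoked recording into four ensemble spike
counts.  Those counts serve two purposes: the maximally firing ensemble is
the classified stimulus, and the counts directly weight the four calibration
force vectors to produce the decoded 2-D force.

:class:`SpikingEnsembleDecoder` packages the pipeline as a scikit-learn
estimator (``fit`` trains the plastic network on labeled recordings with the
teacher protocol; ``predict`` classifies held-out recordings); the
module-level functions are thin functional wrappers used by the closed-loop
code.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit

from . import encoding
from .network import Network, NetworkConfig, build_network
from .synthetic import EvokedRecording

__all__ = [
    "SpikingEnsembleDecoder",
    "train_decoder",
    "decode_recording",
    "classify",
    "counts_to_force",
    "test_accuracy",
]


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Functional core
# ---------------------------------------------------------------------------

def train_decoder(
    network: Network,
    recordings: list[EvokedRecording],
    labels=None,
    seed: int = 0,
    *,
    input_rate_hz: float = encoding.INPUT_RATE_HZ,
    teacher_pos_hz: float = encoding.TEACHER_POS_HZ,
    teacher_neg_hz: float = encoding.TEACHER_NEG_HZ,
    presentation_ms: float = encoding.PRESENTATION_MS,
    window_ms: int = encoding.WINDOW_MS,
) -> Network:
    """Train in one epoch: every trial once, in a seeded random order.

    Each presentation encodes the recording into 400 ms Poisson input trains,
    adds the teacher trains for the trial's label, and runs the network with
    plasticity on.  A per-trial log of potentiation/depression event counts is
    appended to ``network.training_log``.
    """
    if not recordings:
        raise ValueError("empty training set")
    if labels is None:
        labels = [r.stimulus_class for r in recordings]
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(recordings),):
        raise ValueError("labels must match recordings one-to-one")
    if np.any(labels < 1) or np.any(labels > network.config.n_ensembles):
        raise ValueError("labels must be in 1..n_ensembles")

    ss = np.random.SeedSequence([int(seed), 11])
    rng = np.random.default_rng(_seed_int(ss))
    order = rng.permutation(len(recordings))
    for k, idx in enumerate(order):
        rec, lab = recordings[idx], int(labels[idx])
        input_trains = encoding.encode_recording(
            rec, rate_hz=input_rate_hz, duration_ms=presentation_ms,
            window_ms=window_ms, seed=rng,
        )
        teacher = encoding.make_teacher_trains(
            lab, rate_pos_hz=teacher_pos_hz, rate_neg_hz=teacher_neg_hz,
            duration_ms=presentation_ms, seed=rng,
            n_ensembles=network.config.n_ensembles,
        )
        res = network.simulate_presentation(
            input_trains, teacher, presentation_ms, plasticity_on=True
        )
        network.training_log.append(
            {
                "presentation": k,
                "trial": int(idx),
                "label": lab,
                "n_potentiation": res.n_potentiation_events,
                "n_depression": res.n_depression_events,
                "ensemble_counts": res.ensemble_counts.tolist(),
            }
        )
    return network


def decode_recording(
    network: Network,
    recording: EvokedRecording,
    seed: int = 0,
    *,
    input_rate_hz: float = encoding.INPUT_RATE_HZ,
    presentation_ms: float = encoding.PRESENTATION_MS,
    window_ms: int = encoding.WINDOW_MS,
) -> np.ndarray:
    """Decode one recording: plasticity off, no teacher; per-ensemble counts."""
    input_trains = encoding.encode_recording(
        recording, rate_hz=input_rate_hz, duration_ms=presentation_ms,
        window_ms=window_ms, seed=seed,
    )
    res = network.simulate_presentation(
        input_trains, None, presentation_ms, plasticity_on=False
    )
    return res.ensemble_counts


def classify(counts) -> int:
    """Stimulus class of the maximally firing ensemble (1-based).

    Ties break deterministically toward the lowest ensemble index.
    """
    counts = np.asarray(counts)
    return int(np.argmax(counts)) + 1


def counts_to_force(counts, calibration, normalize: bool = True) -> np.ndarray:
    """Weighted sum of the four calibration forces, weighted by the counts.

    With ``normalize`` (default) weights are ``counts / sum(counts)``, so the
    force lies in the convex hull of the calibration forces; zero total count
    gives zero force.  Without it, raw counts weight the sum directly.
    """
    counts = np.asarray(counts, dtype=float)
    forces = np.asarray(getattr(calibration, "forces", calibration), dtype=float)
    if forces.shape != (counts.size, 2):
        raise ValueError("calibration must provide one 2-D force per ensemble")
    total = counts.sum()
    if normalize:
        if total <= 0:
            return np.zeros(2)
        w = counts / total
    else:
        w = counts
    return w @ forces


def test_accuracy(
    network_builder,
    recordings: list[EvokedRecording],
    labels=None,
    n_splits: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Held-out classification accuracy over stratified random splits.

    For each split a fresh network is built (``network_builder(seed) ->
    Network``), trained on the training portion and scored on the held-out
    portion by the maximally-firing-ensemble rule.  Returns one accuracy per
    split.
    """
    if labels is None:
        labels = [r.stimulus_class for r in recordings]
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("dataset must contain more than one class")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_frac, random_state=seed
    )
    ss = np.random.SeedSequence([int(seed), 23])
    children = ss.spawn(n_splits)
    accs = np.empty(n_splits)
    X_idx = np.arange(len(recordings))
    for s, (tr, te) in enumerate(splitter.split(X_idx, labels)):
        split_seed = _seed_int(children[s])
        net = network_builder(split_seed)
        train_decoder(
            net, [recordings[i] for i in tr], labels[tr], seed=split_seed
        )
        correct = 0
        for j, i in enumerate(te):
            counts = decode_recording(net, recordings[i], seed=split_seed + j + 1)
            correct += classify(counts) == labels[i]
        accs[s] = correct / len(te)
    return accs


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class SpikingEnsembleDecoder(BaseEstimator, ClassifierMixin):
    """Spiking-network ensemble decoder as a scikit-learn classifier.

    ``X`` is a list (or array) of :class:`EvokedRecording`; ``y`` holds the
    stimulus classes.  ``fit`` builds the 252-neuron network with seeded
    mismatch jitter and trains it in one epoch with the 75/25 Hz teacher
    protocol; ``predict`` returns the class of the maximally firing ensemble.

    Parameters
    ----------
    network_config : NetworkConfig, optional
        Substrate configuration; the seed inside it is replaced by one
        derived from ``random_state`` so the estimator is fully reproducible.
    input_rate_hz, teacher_pos_hz, teacher_neg_hz : float
        Encoding rates (active input lines; true-class and other-class
        teacher rates).
    presentation_ms : float
        Presentation window per trial.
    window_ms : int
        Portion of the recording that is binned (1 ms bins).
    random_state : int
        Master seed for mismatch jitter, initial synapse states, trial order
        and Poisson train generation.

    Attributes
    ----------
    network_ : Network
        The trained substrate.
    efficacy_ : ndarray of shape (n_neurons, n_lines)
        Binary synaptic weights after training.
    training_log_ : list of dict
        Per-presentation potentiation/depression event counts.
    classes_ : ndarray
        Sorted class labels seen during ``fit``.
    """

    def __init__(
        self,
        network_config: NetworkConfig | None = None,
        input_rate_hz: float = encoding.INPUT_RATE_HZ,
        teacher_pos_hz: float = encoding.TEACHER_POS_HZ,
        teacher_neg_hz: float = encoding.TEACHER_NEG_HZ,
        presentation_ms: float = encoding.PRESENTATION_MS,
        window_ms: int = encoding.WINDOW_MS,
        random_state: int = 0,
    ):
        self.network_config = network_config
        self.input_rate_hz = input_rate_hz
        self.teacher_pos_hz = teacher_pos_hz
        self.teacher_neg_hz = teacher_neg_hz
        self.presentation_ms = presentation_ms
        self.window_ms = window_ms
        self.random_state = random_state

    def _build_network(self) -> Network:
        cfg = self.network_config or NetworkConfig()
        import dataclasses as _dc

        net_seed = _seed_int(np.random.SeedSequence([int(self.random_state), 3]))
        cfg = _dc.replace(cfg, seed=net_seed)
        return build_network(cfg)

    def fit(self, X, y=None):
        X = list(X)
        if y is None:
            y = [r.stimulus_class for r in X]
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        n_ens = (self.network_config or NetworkConfig()).n_ensembles
        if self.classes_.size != n_ens:
            raise ValueError(
                f"need exactly {n_ens} classes, got {self.classes_.size}"
            )
        ens_labels = np.searchsorted(self.classes_, y) + 1  # 1-based ensembles
        self.network_ = self._build_network()
        train_decoder(
            self.network_, X, ens_labels,
            seed=_seed_int(np.random.SeedSequence([int(self.random_state), 5])),
            input_rate_hz=self.input_rate_hz,
            teacher_pos_hz=self.teacher_pos_hz,
            teacher_neg_hz=self.teacher_neg_hz,
            presentation_ms=self.presentation_ms,
            window_ms=self.window_ms,
        )
        self.efficacy_ = self.network_.efficacy
        self.training_log_ = self.network_.training_log
        return self

    def ensemble_counts(self, X) -> np.ndarray:
        """Per-ensemble output spike counts for each recording; shape (n, 4)."""
        self._check_fitted()
        base = np.random.SeedSequence([int(self.random_state), 7])
        out = np.empty((len(X), self.network_.config.n_ensembles), dtype=np.int64)
        for i, rec in enumerate(X):
            out[i] = decode_recording(
                self.network_, rec,
                seed=_seed_int(np.random.SeedSequence([int(self.random_state), 7, i])),
                input_rate_hz=self.input_rate_hz,
                presentation_ms=self.presentation_ms,
                window_ms=self.window_ms,
            )
        return out

    def decision_function(self, X) -> np.ndarray:
        return self.ensemble_counts(X).astype(float)

    def predict(self, X) -> np.ndarray:
        counts = self.ensemble_counts(X)
        return self.classes_[np.argmax(counts, axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("decoder is not fitted; call fit first")
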