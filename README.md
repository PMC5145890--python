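# snnbmi

A simulator of a closed-loop, bidirectional brain–machine interface whose
decoder is a spiking neural network with on-line, calcium-gated bistable
plasticity.

## The problem

In a bidirectional BMI, a *decoder* turns recorded cortical activity into
motor commands for an external object, while an *encoder* feeds the object's
state back to the brain as patterns of intracortical microstimulation (ICMS),
closing the loop. This package models such a system end to end: stimulus-
evoked multi-channel spike recordings (four stimulation classes, 15
channels) are decoded by a 252-neuron spiking network into a 2-D force that
drives an object across a 38 × 38 cm workspace toward a central target, and
the object's position selects the next stimulus. Because the original
evoked recordings are not publicly available, a first-class synthetic
generator reproduces their statistical structure (a shared post-stimulus
transient, class-specific spike-timing features with partial overlap between
classes, class-dependent total spike counts, Poisson trial-to-trial
variability, statistically interchangeable channels).

The package is aimed at researchers studying spike-based decoding,
neuromorphic-style on-line learning rules, and closed-loop sensorimotor
control policies.

## The model

**Temporal-to-spatial code.** The 15 channels are merged into one spike
train; the first 256 ms after stimulation offset are binned at 1 ms; each
occupied bin drives one of 256 input lines with a 400 ms, 100 Hz Poisson
train (empty bins drive nothing).

**Decoder network.** 252 linear-leak integrate-and-fire neurons, grouped in
four ensembles of 63, each neuron owning one plastic synapse per input line.
Synapses are bistable: an internal variable x jumps on pre-synaptic spikes —
potentiation if the post-synaptic membrane is depolarized (V > θ_V) and the
calcium trace is in a window [θ↑_l, θ↑_h), depression if the membrane is low
and calcium is in [θ↓_l, θ↓_h) — and drifts between spikes toward 0 or x_max
across a bistability threshold. The expressed weight is binary. The upper
calcium bound implements *stop-learning*: a neuron firing fast enough stops
potentiating, capping its input and creating heterosynaptic competition.
During training each trial is presented with a teacher: 75 Hz Poisson drive
to the true-class ensemble, 25 Hz to the others. Fabrication-style mismatch
(10 % CV on thresholds, leak, plasticity gates, teacher weight) turns each
ensemble into 63 slightly different weak classifiers.

**Force readout.** The per-ensemble output spike counts n_k weight the four
calibration forces F_k (unit vectors from each sensory region's centroid to
the target): F = Σ_k (n_k / Σ n) F_k. The maximally firing ensemble is also
the classified stimulus.

**Closed loop.** The workspace splits into four quadrant regions; encoder ON
maps the position to its region's stimulus class, encoder OFF draws a class
at random. Each step decodes a held-out recording of that class and
displaces the object by `gain` times a low-pass-filtered force (an object
with inertia). A trial ends on entering the 3.6 cm target region or after
100 steps.

## Worked example

```python
import numpy as np
from snnbmi import *
from snnbmi.config import make_fixture
from snnbmi.decoder import train_decoder, decode_recording, classify, counts_to_force

fx = make_fixture("paper-like", seed=1)          # 160 train + 40 test recordings
net = build_network(NetworkConfig(seed=101))
train_decoder(net, fx["train"], seed=201)         # one epoch, teacher protocol

ws = build_workspace(); field = calibrate_field(ws)
rec = fx["test"][12]
counts = decode_recording(net, rec, seed=0)
print("true class:", rec.stimulus_class)          # true class: 2
print("ensemble counts:", counts)                 # ensemble counts: [ 40 127  60  26]
print("predicted:", classify(counts))             # predicted: 2
print("force:", np.round(counts_to_force(counts, field), 3))
                                                  # force: [ 0.338 -0.226]

traj = run_trial(net, ws, field, fx["test"], ws.start_positions[1],
                 mode="on", stop_rule="target_region", seed=5)
print(traj.converged, traj.steps_used)            # True 16
```

The decoded counts show the class-2 ensemble firing most (127 of 253 output
spikes), so the recording is classified as stimulus 2 and the decoded force
points from region 2 toward the target; the closed-loop trial reaches the
target region in 16 steps.

The same pipeline is exposed as a scikit-learn classifier
(`SpikingEnsembleDecoder().fit(recordings).predict(...)`) and as a CLI
(`snnbmi run-all --seed 1 --out out/`).

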