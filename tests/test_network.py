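import dataclasses

import numpy as np
import pytest

from snnbmi.events import EventStream
from snnbmi.network import (
    Network,
    NetworkConfig,
    NeuronParams,
    NeuronState,
    PlasticityParams,
    PlasticSynapse,
    build_network,
    drift_synapse,
    on_pre_spike,
    step_neuron,
    update_calcium,
)


# ---------------------------------------------------------------------------
# Independent reference: a direct per-step transcription of the update rules,
# used as the oracle for the vectorized kernel.
# ---------------------------------------------------------------------------

def reference_simulate(net: Network, input_stream, teacher_stream, duration_ms, plasticity_on):
    cfg = net.config
    np_, pp = cfg.neuron_params, cfg.plasticity_params
    dt = cfg.dt_ms
    n_steps = int(round(duration_ms / dt))
    n, m = net.x.shape
    x = net.x.copy()
    v = np.zeros(n)
    ca = np.zeros(n)
    refr = np.zeros(n, dtype=int)
    counts = np.zeros(n, dtype=int)
    refr_steps = int(round(np_.refractory_ms / dt))
    decay = np.exp(-dt / np_.tau_ca)
    n_pot = n_dep = 0
    total_drive = 0.0

    def events_by_step(stream):
        d = {}
        if stream is not None:
            for t, a in zip(stream.times, stream.addresses):
                s = min(int(t / dt), n_steps - 1)
                d.setdefault(s, []).append(int(a))
        return d

    ev = events_by_step(input_stream)
    te = events_by_step(teacher_stream)

    for s in range(n_steps):
        drive = np.zeros(n)
        for line in ev.get(s, []):
            for nn in range(n):
                w = pp.j_high if x[nn, line] >= pp.theta_x else pp.j_low
                drive[nn] += w
                total_drive += w
            if plasticity_on:
                for nn in range(n):
                    if v[nn] > net.theta_v[nn] and net.ca_up_low[nn] <= ca[nn] < net.ca_up_high[nn]:
                        new = min(x[nn, line] + pp.a_up, pp.x_max)
                        n_pot += new > x[nn, line]
                        x[nn, line] = new
                    elif v[nn] <= net.theta_v[nn] and net.ca_dn_low[nn] <= ca[nn] < net.ca_dn_high[nn]:
                        new = max(x[nn, line] - pp.b_down, 0.0)
                        n_dep += new < x[nn, line]
                        x[nn, line] = new
        for e in te.get(s, []):
            for nn in range(n):
                if net.ensemble_of[nn] == e:
                    drive[nn] += net.teacher_eff[nn]
        for nn in range(n):
            ca[nn] *= decay
            if refr[nn] > 0:
                refr[nn] -= 1
                continue
            vv = max(0.0, v[nn] - net.leak[nn] * dt + drive[nn])
            if vv >= net.v_thresh[nn]:
                counts[nn] += 1
                ca[nn] += np_.j_ca
                vv = np_.v_reset
                refr[nn] = refr_steps
            v[nn] = vv
        if plasticity_on:
            above = x > pp.theta_x
            below = x < pp.theta_x
            x[above] = np.minimum(x[above] + pp.drift_up * dt, pp.x_max)
            x[below] = np.maximum(x[below] - pp.drift_dn * dt, 0.0)
    return counts, x, n_pot, n_dep, total_drive


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

class TestBuild:
    def test_default_synapse_budget(self):
        net = build_network(NetworkConfig())
        assert net.x.shape == (252, 256)
        assert net.x.size == 64512

    def test_zero_mismatch_gives_identical_neurons(self):
        cfg = NetworkConfig(neuron_params=NeuronParams(mismatch_cv=0.0))
        net = build_network(cfg)
        for arr in (net.v_thresh, net.leak, net.theta_v, net.ca_up_high, net.teacher_eff):
            assert np.ptp(arr) == 0.0

    def test_same_seed_same_jitter(self):
        a, b = build_network(NetworkConfig(seed=9)), build_network(NetworkConfig(seed=9))
        assert np.array_equal(a.v_thresh, b.v_thresh)
        assert np.array_equal(a.leak, b.leak)
        assert np.array_equal(a.x, b.x)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_neurons=100, n_ensembles=4, ensemble_size=63)

    def test_x_init_modes(self, tiny_config):
        dep = build_network(tiny_config)
        assert np.all(dep.x == 0.0)
        uni = build_network(dataclasses.replace(tiny_config, x_init="uniform"))
        assert uni.x.min() >= 0 and uni.x.max() <= 1 and uni.x.std() > 0


# ---------------------------------------------------------------------------
# Single-neuron operations
# ---------------------------------------------------------------------------

class TestNeuron:
    def test_no_drive_never_spikes(self):
        p = NeuronParams()
        s = NeuronState(v=p.v_reset)
        for _ in range(1000):
            s, spiked = step_neuron(s, 0.0, 0.1, p)
            assert not spiked
        assert s.v == 0.0  # floored at zero

    def test_constant_drive_matches_closed_form_rate(self):
        # rate = 1 / (refractory + (v_thresh - v_reset)/(I - leak)) per ms
        p = NeuronParams(leak=0.05, refractory_ms=2.0, mismatch_cv=0.0)
        I, dt, T = 0.137, 0.1, 4000.0
        s = NeuronState()
        spikes = 0
        for _ in range(int(T / dt)):
            s, spiked = step_neuron(s, I * dt, dt, p)
            spikes += spiked
        expected = 1.0 / (p.refractory_ms + (p.v_thresh - p.v_reset) / (I - p.leak))
        assert spikes / T == pytest.approx(expected, rel=0.02)

    def test_threshold_crossing_resets(self):
        p = NeuronParams()
        s, spiked = step_neuron(NeuronState(), p.v_thresh + 0.01, 0.1, p)
        assert spiked and s.v == p.v_reset and s.refractory_remaining == p.refractory_ms
        s, spiked = step_neuron(s, p.v_thresh, 0.1, p)
        assert not spiked  # refractory: no integration


class TestCalcium:
    def test_pure_decay(self):
        p = NeuronParams(tau_ca=20.0)
        s = NeuronState(ca=2.0)
        for _ in range(100):
            s = update_calcium(s, False, 0.5, p)
        assert s.ca == pytest.approx(2.0 * np.exp(-50.0 / 20.0), rel=1e-9)

    def test_zero_increment_stays_zero(self):
        p = NeuronParams(j_ca=0.0)
        s = update_calcium(NeuronState(), True, 0.1, p)
        assert s.ca == 0.0

    def test_steady_state_tracks_rate(self):
        # mean calcium of a neuron firing at rate r -> j_ca * r * tau_ca
        p = NeuronParams(leak=0.05, tau_ca=50.0, j_ca=1.0, mismatch_cv=0.0)
        I, dt = 0.137, 0.1
        s = NeuronState()
        vals, spikes = [], 0
        for k in range(int(6000 / dt)):
            s, spiked = step_neuron(s, I * dt, dt, p)
            s = update_calcium(s, spiked, dt, p)
            spikes += spiked
            if k * dt > 1000:
                vals.append(s.ca)
        rate = spikes / 6000.0
        assert np.mean(vals) == pytest.approx(p.j_ca * rate * p.tau_ca, rel=0.05)


class TestPlasticityRules:
    pp = PlasticityParams()

    def test_stop_learning_blocks_potentiation_at_high_calcium(self):
        syn = PlasticSynapse(x=0.2)
        out = on_pre_spike(syn, v_post=1.0, ca_post=self.pp.theta_ca_up_high + 1, params=self.pp)
        assert out.x == syn.x

    def test_potentiation_inside_window(self):
        syn = on_pre_spike(PlasticSynapse(0.2), 1.0, self.pp.theta_ca_up_low, self.pp)
        assert syn.x == pytest.approx(0.2 + self.pp.a_up)

    def test_ceiling_and_floor_saturate(self):
        up = on_pre_spike(PlasticSynapse(self.pp.x_max), 1.0, self.pp.theta_ca_up_low, self.pp)
        assert up.x == self.pp.x_max
        dn = on_pre_spike(PlasticSynapse(0.0), 0.0, self.pp.theta_ca_dn_low, self.pp)
        assert dn.x == 0.0

    def test_depression_requires_low_membrane(self):
        ca = self.pp.theta_ca_dn_low
        dep = on_pre_spike(PlasticSynapse(0.8), self.pp.theta_v, ca, self.pp)
        assert dep.x == pytest.approx(0.8 - self.pp.b_down)
        # same calcium, depolarized membrane: no depression
        same = on_pre_spike(PlasticSynapse(0.8), self.pp.theta_v + 0.5, ca, self.pp)
        assert same.x == 0.8 or same.x == pytest.approx(0.8 + self.pp.a_up)

    def test_drift_attractors_and_fixed_point(self):
        pp = self.pp
        assert drift_synapse(PlasticSynapse(pp.theta_x + 0.01), 1e6, pp).x == pp.x_max
        assert drift_synapse(PlasticSynapse(pp.theta_x - 0.01), 1e6, pp).x == 0.0
        assert drift_synapse(PlasticSynapse(pp.theta_x), 1e6, pp).x == pp.theta_x

    def test_drift_closed_form_matches_small_step_integration(self):
        pp = self.pp
        for x0 in (0.05, 0.4, 0.51, 0.93):
            syn = PlasticSynapse(x0)
            for _ in range(200):
                syn = drift_synapse(syn, 0.5, pp)
            assert drift_synapse(PlasticSynapse(x0), 100.0, pp).x == pytest.approx(syn.x, abs=1e-12)


# ---------------------------------------------------------------------------
# Full presentations
# ---------------------------------------------------------------------------

def poisson_stream(rng, lines, rate_hz, duration):
    ts, ads = [], []
    for ln in lines:
        n = rng.poisson(rate_hz * duration / 1000.0)
        ts.append(rng.uniform(0, duration, n))
        ads.append(np.full(n, ln))
    return EventStream(np.concatenate(ts), np.concatenate(ads).astype(np.int64))


class TestSimulatePresentation:
    def test_silent_input_silent_output(self, tiny_config):
        net = build_network(tiny_config)
        res = net.simulate_presentation(EventStream(), None, 100.0, plasticity_on=True)
        assert res.neuron_counts.sum() == 0
        assert res.total_injected_drive == 0.0

    def test_matches_reference_implementation(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, dt_ms=0.5, x_init="uniform")
        rng = np.random.default_rng(3)
        for plast in (False, True):
            net = build_network(cfg)
            ref_net = build_network(cfg)
            inp = poisson_stream(rng, [0, 3, 7], 400.0, 80.0)
            tea = poisson_stream(rng, [0, 1], 300.0, 80.0)
            tea = EventStream(tea.times, tea.addresses % cfg.n_ensembles)
            exp_counts, exp_x, exp_pot, exp_dep, exp_drive = reference_simulate(
                ref_net, inp, tea, 80.0, plast
            )
            res = net.simulate_presentation(inp, tea, 80.0, plasticity_on=plast)
            assert np.array_equal(res.neuron_counts, exp_counts)
            assert np.allclose(net.x, exp_x, atol=1e-12)
            assert res.n_potentiation_events == exp_pot
            assert res.n_depression_events == exp_dep
            assert res.total_injected_drive == pytest.approx(exp_drive, rel=1e-12)

    def test_plasticity_off_freezes_weights(self, tiny_config):
        net = build_network(dataclasses.replace(tiny_config, x_init="uniform"))
        x0 = net.x.copy()
        inp = poisson_stream(np.random.default_rng(0), range(16), 200.0, 200.0)
        net.simulate_presentation(inp, None, 200.0, plasticity_on=False)
        assert np.array_equal(net.x, x0)

    def test_injected_drive_audits_efficacy_sum(self, tiny_config):
        net = build_network(tiny_config)
        pp = net.config.plasticity_params
        net.x[:] = pp.x_max  # all potentiated, frozen
        inp = poisson_stream(np.random.default_rng(1), [2, 5], 100.0, 100.0)
        res = net.simulate_presentation(inp, None, 100.0, plasticity_on=False)
        assert res.total_injected_drive == pytest.approx(
            len(inp) * pp.j_high * net.config.n_neurons
        )

    def test_efficacy_is_binary_everywhere(self, tiny_config):
        net = build_network(dataclasses.replace(tiny_config, x_init="uniform"))
        inp = poisson_stream(np.random.default_rng(2), range(16), 300.0, 150.0)
        tea = poisson_stream(np.random.default_rng(3), range(4), 150.0, 150.0)
        net.simulate_presentation(inp, tea, 150.0, plasticity_on=True)
        pp = net.config.plasticity_params
        assert set(np.unique(net.efficacy)) <= {pp.j_low, pp.j_high}
        assert net.x.min() >= 0.0 and net.x.max() <= pp.x_max

    def test_stop_learning_blocks_all_potentiation_at_high_rate(self):
        # teacher drives ensemble 1 far above the stop threshold before any
        # input arrives; pre-synaptic events then cause zero potentiations
        cfg = NetworkConfig(seed=4)
        net = build_network(cfg)
        rng = np.random.default_rng(5)
        n_tea = 200
        tea = EventStream(np.sort(rng.uniform(0, 400, n_tea)), np.zeros(n_tea, dtype=np.int64))
        inp_t = np.sort(rng.uniform(150, 400, 30))
        inp = EventStream(inp_t, np.zeros(30, dtype=np.int64))
        res = net.simulate_presentation(inp, tea, 400.0, plasticity_on=True)
        ens1 = res.ensemble_counts[0]
        assert ens1 / 63 / 0.4 > 100.0  # ensemble actually driven hard
        assert res.n_potentiation_events == 0

    def test_halving_dt_changes_counts_by_under_5_percent(self):
        rng = np.random.default_rng(6)
        lines = rng.choice(256, 80, replace=False)
        inp = poisson_stream(rng, lines, 100.0, 400.0)

        def counts(dt):
            net = build_network(NetworkConfig(dt_ms=dt, seed=11))
            net.x[:, lines] = net.config.plasticity_params.x_max
            return net.simulate_presentation(inp, None, 400.0, plasticity_on=False).ensemble_counts

        c1, c2 = counts(0.1), counts(0.05)
        assert c1.sum() > 500
        assert np.all(np.abs(c1 - c2) / c1 < 0.05)

    def test_events_beyond_duration_rejected(self, tiny_config):
        net = build_network(tiny_config)
        bad = EventStream(np.array([500.0]), np.array([0]))
        with pytest.raises(ValueError):
            net.simulate_presentation(bad, None, 400.0, plasticity_on=False)

    def test_repeat_run_bit_identical(self, tiny_config):
        inp = poisson_stream(np.random.default_rng(7), [1, 2], 200.0, 100.0)
        a = build_network(tiny_config).simulate_presentation(inp, None, 100.0, False)
        b = build_network(tiny_config).simulate_presentation(inp, None, 100.0, False)
        assert np.array_equal(a.neuron_counts, b.neuron_counts)


def test_checkpoint_roundtrip(tmp_path, tiny_config):
    net = build_network(dataclasses.replace(tiny_config, x_init="uniform"))
    inp = poisson_stream(np.random.default_rng(8), range(8), 200.0, 100.0)
    net.simulate_presentation(inp, None, 100.0, plasticity_on=True)
    p = tmp_path / "net.json"
    net.save(p)
    back = Network.load(p)
    assert np.array_equal(back.x, net.x)
    res_a = net.simulate_presentation(inp, None, 100.0, plasticity_on=False)
    res_b = back.simulate_presentation(inp, None, 100.0, plasticity_on=False)
    assert np.array_equal(res_a.neuron_counts, res_b.neuron_counts)
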