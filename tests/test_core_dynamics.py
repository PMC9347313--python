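"""Single-neuron membrane, synaptic current, and short-term plasticity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semnet import core_dynamics as cd
from semnet.params import ModelParams, NeuronParams, StpParams, ReceptorParams


class TestAdex:
    def test_subthreshold_relaxation_time_constant(self, default_params):
        """A small perturbation relaxes with tau ~= C_m/g_L = 20 ms."""
        p = default_params.neuron
        V0 = cd.resting_potential(p)
        t, V, _ = cd.simulate_voltage(p, default_params.receptors, 120.0, 0.001,
                                      {}, V0=V0 + 1.0)
        dev = V - V0
        # time to decay to 1/e of the initial 1 mV deviation
        idx = np.argmax(dev < 1.0 / np.e)
        tau_eff = t[idx]
        assert tau_eff == pytest.approx(p.tau_m, rel=0.10)

    def test_resting_potential_near_leak_reversal(self, default_params):
        V_star = cd.resting_potential(default_params.neuron)
        assert abs(V_star - default_params.neuron.E_L) < 0.1

    def test_spike_reset_and_adaptation_increment(self, default_params):
        p = default_params.neuron
        state = cd.NeuronState.at_rest(p)
        spiked = False
        for _ in range(10000):
            state, spiked = cd.adex_step(state, p, 0.0, 1500.0, 0.1)
            if spiked:
                break
        assert spiked
        assert state.V_m == pytest.approx(p.V_r)  # -60 mV
        assert state.I_w == pytest.approx(p.b, rel=0.01)  # 86 pA
        assert state.refractory_remaining == pytest.approx(p.tau_ref)

    def test_adaptation_decays_exponentially_after_spike(self, default_params):
        """With no further input, I_w(t) = b * exp(-t / tau_Iw)."""
        p = default_params.neuron
        state = cd.NeuronState(V_m=p.E_L, I_w=p.b)
        dt, t_total = 0.01, 280.0
        for _ in range(int(t_total / dt)):
            state, _ = cd.adex_step(state, p, 0.0, -2000.0, dt)  # hold subthreshold
        assert state.I_w == pytest.approx(p.b * np.exp(-1.0), rel=0.01)

    def test_refractory_period_enforced(self, default_params):
        """No two spikes closer than tau_ref = 5 ms under strong drive."""
        p = default_params.neuron
        t, V, spikes = cd.simulate_voltage(
            p, default_params.receptors, 500.0, 0.1, {}, I_ext=3000.0
        )
        assert len(spikes) > 10
        assert np.all(np.diff(spikes) >= p.tau_ref - 1e-9)

    def test_dt_halving_stability(self, default_params):
        """Halving dt from 0.1 to 0.05 ms shifts spike times < 0.5 ms over 1 s.

        Frozen input: a fixed schedule of strong excitatory conductance
        events, each eliciting one spike.
        """
        p = default_params.neuron
        events = {0: [(t, 60.0) for t in np.arange(50.0, 1000.0, 100.0)]}
        out = {}
        for dt in (0.1, 0.05):
            _, _, spikes = cd.simulate_voltage(
                p, default_params.receptors, 1000.0, dt, events
            )
            out[dt] = spikes
        assert len(out[0.1]) == len(out[0.05]) == 10
        assert np.max(np.abs(out[0.1] - out[0.05])) < 0.5

    def test_invalid_arguments(self, default_params):
        p = default_params.neuron
        with pytest.raises(ValueError):
            cd.adex_step(cd.NeuronState.at_rest(p), p, 0.0, 0.0, dt=-0.1)
        with pytest.raises(ValueError):
            cd.adex_step(cd.NeuronState(V_m=np.nan), p, 0.0, 0.0, dt=0.1)


class TestSynapticCurrent:
    def test_zero_driving_force(self):
        assert cd.synaptic_current(0.0, {"AMPA": 3.0}) == pytest.approx(0.0)
        assert cd.synaptic_current(-75.0, {"GABA": 5.0}) == pytest.approx(0.0)

    def test_gaba_hyperpolarizing_magnitude(self):
        """7 nS GABA at -60 mV: 105 pA of hyperpolarizing current."""
        I = cd.synaptic_current(-60.0, {"GABA": 7.0})
        assert I == pytest.approx(-105.0)

    def test_ampa_depolarizing_below_reversal(self):
        assert cd.synaptic_current(-70.0, {"AMPA": 1.0}) > 0

    def test_zero_conductances(self):
        assert cd.synaptic_current(-65.0, {}) == 0.0
        assert cd.synaptic_current(-65.0, {"AMPA": 0.0, "NMDA": 0.0}) == 0.0

    def test_unknown_receptor_rejected(self):
        with pytest.raises(ValueError, match="unknown receptor"):
            cd.synaptic_current(-65.0, {"GLYCINE": 1.0})


class TestStp:
    def test_fixed_point_without_spikes(self):
        p = StpParams()
        s = cd.StpState(u=0.7, x=0.2)
        for _ in range(20000):
            s, _ = cd.stp_update(s, p, spike=False, dt=5.0)
        assert s.u == pytest.approx(0.0, abs=1e-3)
        assert s.x == pytest.approx(1.0, abs=1e-3)

    def test_single_spike_jumps(self):
        """From (u=0, x=1) one spike gives (0.2, 0.8) and releases u+ * x- = 0.2."""
        p = StpParams()
        s, release = cd.stp_update(cd.StpState(), p, spike=True, dt=1e-9)
        assert s.u == pytest.approx(p.U)
        assert s.x == pytest.approx(1.0 - p.U)
        assert release == pytest.approx(p.U)

    @pytest.mark.parametrize("rate_hz", [5.0, 20.0, 50.0])
    def test_periodic_train_matches_event_oracle(self, rate_hz):
        """Fine-step clock updates reproduce the exact event-driven solution."""
        p = StpParams()
        isi = 1000.0 / rate_hz
        times = np.arange(1, 41) * isi
        u_ev, x_ev, rel_ev = cd.stp_release_train(times, p)

        dt = 0.01
        s = cd.StpState()
        releases = []
        n = int((times[-1] + 1) / dt)
        spike_steps = set(np.round(times / dt).astype(int))
        for k in range(1, n + 1):
            s, rel = cd.stp_update(s, p, spike=k in spike_steps, dt=dt)
            if rel > 0:
                releases.append(rel)
        assert len(releases) == len(rel_ev)
        np.testing.assert_allclose(releases, rel_ev, rtol=1e-3)

    def test_augmentation_disabled_pins_u(self):
        p = StpParams(enabled=False)
        s = cd.StpState()
        for _ in range(5):
            s, _ = cd.stp_update(s, p, spike=True, dt=10.0)
        assert s.u == pytest.approx(p.U)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_bounds_under_arbitrary_trains(self, spikes):
        p = StpParams()
        s = cd.StpState()
        for spk in spikes:
            s, _ = cd.stp_update(s, p, spike=spk, dt=2.0)
            assert 0.0 <= s.u <= 1.0
            assert 0.0 <= s.x <= 1.0


class TestPoissonBackground:
    def test_zero_rate_empty(self):
        rng = np.random.default_rng(0)
        exc, inh = cd.poisson_background(0.0, 1.5, 1000.0, 0.1, rng)
        assert exc.sum() == 0 and inh.sum() == 0

    def test_event_counts(self):
        """650 Hz over 10 s: each stream within 3 sigma of 6500 events."""
        rng = np.random.default_rng(1)
        exc, inh = cd.poisson_background(650.0, 1.5, 10_000.0, 0.1, rng)
        sigma = np.sqrt(6500.0)
        assert abs(exc.sum() - 6500) < 3 * sigma
        assert abs(inh.sum() - 6500) < 3 * sigma

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            cd.poisson_background(-1.0, 1.5, 10.0, 0.1, np.random.default_rng(0))

    def test_zero_mean_at_symmetric_point(self, default_params):
        """At the midpoint of the two reversals the mean injected current is 0."""
        rng = np.random.default_rng(2)
        exc, inh = cd.poisson_background(650.0, 1.5, 10_000.0, 0.1, rng)
        rec = default_params.receptors
        V_mid = 0.5 * (rec.reversal(0) + rec.reversal(2))
        # equal mean conductances, opposite equal driving forces
        I_mean = (exc.mean() * (rec.reversal(0) - V_mid)
                  + inh.mean() * (rec.reversal(2) - V_mid)) * 1.5
        drive = 1.5 * exc.mean() * abs(rec.reversal(0) - V_mid)
        assert abs(I_mean) < 0.05 * drive


class TestParamValidation:
    def test_neuron_invariants(self):
        with pytest.raises(ValueError):
            NeuronParams(C_m=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(V_r=-50.0, V_t=-55.0)

    def test_stp_invariants(self):
        with pytest.raises(ValueError):
            StpParams(U=1.5)
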