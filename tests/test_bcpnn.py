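"""Bayesian-Hebbian trace cascade: Z/P dynamics, weights, bias, kappa gating."""

import numpy as np
import pytest

from semnet.bcpnn import (
    BcpnnTraces, TraceBank, p_update, run_traces, weight_and_bias, z_update,
)
from semnet.params import BcpnnParams


@pytest.fixture
def params():
    return BcpnnParams()


class TestZTrace:
    def test_decays_to_epsilon_without_spikes(self, params):
        Z = 0.8
        for _ in range(5000):
            Z = z_update(Z, 0, params.tau_z_nmda, params, dt=1.0)
        assert Z == pytest.approx(params.epsilon, rel=1e-6)

    @pytest.mark.parametrize("tau_z", [5.0, 100.0])
    def test_sustained_fmax_firing_averages_to_one(self, params, tau_z):
        """Periodic firing at f_max gives a time-averaged Z of ~1."""
        dt = 0.1
        isi_steps = int(round(1000.0 / params.f_max / dt))
        Z, acc, n = params.epsilon, 0.0, 0
        for k in range(400 * isi_steps):
            Z = z_update(Z, int(k % isi_steps == 0), tau_z, params, dt)
            if k > 100 * isi_steps:  # skip transient
                acc += Z
                n += 1
        assert acc / n == pytest.approx(1.0, rel=0.02)

    def test_kappa_has_no_effect_on_z(self, params):
        import dataclasses

        p2 = dataclasses.replace(params, kappa=0.0)
        z1 = z_update(0.5, 1, 5.0, params, 0.1)
        z2 = z_update(0.5, 1, 5.0, p2, 0.1)
        assert z1 == z2


class TestPTrace:
    def test_kappa_zero_freezes(self, params):
        tr = BcpnnTraces(Z_i=0.9, Z_j=0.8, P_i=0.1, P_j=0.2, P_ij=0.05)
        out = p_update(tr, params, dt=50.0, kappa=0.0)
        assert (out.P_i, out.P_j, out.P_ij) == (0.1, 0.2, 0.05)

    def test_relaxation_time_constant(self, params):
        """Constant Z = c: P approaches c with time constant tau_p/kappa = 15 s."""
        c = 0.6
        tr = BcpnnTraces(Z_i=c, Z_j=c, P_i=0.0 + params.epsilon,
                         P_j=params.epsilon, P_ij=c * c)
        dt = 10.0
        for _ in range(int(params.tau_p / dt)):  # integrate one tau_p
            tr = p_update(tr, params, dt)
        expected = c + (params.epsilon - c) * np.exp(-1.0)
        assert tr.P_i == pytest.approx(expected, rel=0.01)

    def test_independent_trains_factorize(self, params):
        """For independent pre/post Poisson trains, <P_ij> -> <P_i><P_j>."""
        rng = np.random.default_rng(5)
        rate, dur = 10.0, 200_000.0
        ratios = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pre = np.sort(rng.uniform(0, dur, int(rate * dur / 1000)))
            post = np.sort(rng.uniform(0, dur, int(rate * dur / 1000)))
            df = run_traces(pre, post, params, tau_z=params.tau_z_nmda,
                            duration=dur, dt=1.0, record_every=100)
            tail = df[df.t > dur / 2]
            ratios.append(tail.P_ij.mean() / (tail.P_i.mean() * tail.P_j.mean()))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestWeightAndBias:
    def test_independence_gives_zero_weight(self, params):
        tr = BcpnnTraces(1, 1, P_i=0.3, P_j=0.2, P_ij=0.06)
        w, _ = weight_and_bias(tr, params, bank="nmda")
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_log_odds(self, params):
        """P_i = P_j = P_ij = 0.5 with the fast-bank gain: w = 0.76 ln 2."""
        tr = BcpnnTraces(1, 1, P_i=0.5, P_j=0.5, P_ij=0.5)
        w, _ = weight_and_bias(tr, params, bank="ampa")
        assert w == pytest.approx(0.76 * np.log(2.0), rel=1e-9)

    def test_full_certainty_gives_zero_bias(self, params):
        tr = BcpnnTraces(1, 1, P_i=0.5, P_j=1.0, P_ij=0.5)
        _, beta = weight_and_bias(tr, params)
        assert beta == pytest.approx(0.0)

    def test_nonpositive_traces_rejected(self, params):
        tr = BcpnnTraces(1, 1, P_i=0.0, P_j=0.5, P_ij=0.1)
        with pytest.raises(ValueError):
            weight_and_bias(tr, params)

    def test_weights_can_be_negative(self, params):
        tr = BcpnnTraces(1, 1, P_i=0.5, P_j=0.5, P_ij=0.1)
        w, _ = weight_and_bias(tr, params)
        assert w < 0


class TestSymmetryAndBank:
    def test_mirrored_trains_give_symmetric_weights(self, params):
        """Swapping pre and post trains leaves the log-odds weight unchanged."""
        rng = np.random.default_rng(11)
        a = np.sort(rng.uniform(0, 5000, 60))
        b = np.sort(rng.uniform(0, 5000, 80))
        kw = dict(params=params, tau_z=params.tau_z_nmda, duration=5000.0,
                  dt=0.5, record_every=2000)
        fwd = run_traces(a, b, **kw).iloc[-1]
        bwd = run_traces(b, a, **kw).iloc[-1]
        w_fwd = np.log(fwd.P_ij / (fwd.P_i * fwd.P_j))
        w_bwd = np.log(bwd.P_ij / (bwd.P_i * bwd.P_j))
        assert w_fwd == pytest.approx(w_bwd, rel=1e-9)

    def test_trace_bank_checkpoint_roundtrip(self, params):
        bank = TraceBank.create(5, params, tau_z=params.tau_z_nmda)
        bank.traces.P_ij[:] = np.linspace(0.01, 0.05, 5)
        df = bank.to_frame()
        restored = TraceBank.from_frame(df, params, tau_z=params.tau_z_nmda)
        np.testing.assert_allclose(restored.traces.P_ij, bank.traces.P_ij)

    def test_set_kappa_validates(self, params):
        bank = TraceBank.create(3, params, tau_z=5.0)
        bank.set_kappa([0, 2], 2.0)
        np.testing.assert_allclose(bank.kappa, [2.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            bank.set_kappa([0], -1.0)


class TestInitialization:
    def test_naive_prior_gives_zero_weight_and_floor_bias(self, params):
        tr = BcpnnTraces.initial(params)
        w, beta = weight_and_bias(tr, params)
        assert w == pytest.approx(0.0)
        assert beta == pytest.approx(params.beta_gain * np.log(params.epsilon))


class TestKappaModulation:
    def _final_w(self, df):
        row = df.iloc[-1]
        return float(np.log(row.P_ij / (row.P_i * row.P_j)))

    def test_boost_strengthens_memory_traces(self, params):
        """Raising kappa during a pairing's encoding epoch builds a stronger
        coactivation trace (and a stronger postsynaptic activation estimate,
        hence a higher bias) than baseline learning on the same spike trains.

        Note the log-odds *weight* of an isolated pairing learned from the
        naive prior is not increased by the boost: all three probability
        estimates inflate together and the prior product grows faster than
        the joint.  The retention advantage is carried by the coactivation
        trace and the intrinsic-excitability bias (see the methods note).
        """
        pre = np.arange(50.0, 2000.0, 40.0)   # 25 Hz for 2 s
        post = pre + 5.0
        kw = dict(params=params, tau_z=params.tau_z_nmda, duration=4000.0,
                  dt=0.5, record_every=500)
        base = run_traces(pre, post, **kw).iloc[-1]
        boosted = run_traces(
            pre, post, kappa_schedule=lambda t: 2.0 if t < 2000.0 else 1.0, **kw
        ).iloc[-1]
        assert boosted.P_ij > base.P_ij
        assert boosted.P_j > base.P_j  # higher bias for the boosted target
        assert self._final_w(run_traces(pre, post, **kw)) > 0
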