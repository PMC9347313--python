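"""Clock-driven spiking network engine (compiled kernel).

Forward-Euler integration at ``dt`` (0.1 ms default) of the whole two-network
model: AdEx membranes, four exponential conductance buffers per neuron
(fast/slow excitatory at 0 mV, fast/slow inhibitory at -75 mV), delayed spike
delivery through a ring buffer, per-neuron Tsodyks-Markram short-term
plasticity on every glutamatergic (pyramidal-sourced) synapse, and the
associative plasticity rule: spike-based BCPNN (two trace banks per synapse
plus a per-neuron bias trace) or multiplicative nearest-neighbor STDP.

Negative weights — preloaded competition and negative BCPNN log-odds weights
alike — are delivered as conductance at the inhibitory reversal with their
bank's own kinetics (the monosynaptic stand-in for disynaptic inhibition);
positive weights go to the excitatory buffers.

The update rules are numerically identical to the reference functions in
:mod:`semnet.core_dynamics` and :mod:`semnet.bcpnn`: exponential decay
between events, jumps at spikes, exponential-Euler relaxation for the P
traces (refreshed every ``p_update_interval``, 1 ms default).  Background
and stimulus Poisson drive is realized as per-step Bernoulli events
(rate*dt is at most ~0.065 here, so multiple events per step are rare).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .network import Network
from .params import ModelParams

RULE_BCPNN, RULE_STDP = 0, 1

# schedule event kinds
EV_BG_RATE, EV_STIM_RATE, EV_STIM_G, EV_KAPPA_SYN, EV_KAPPA_NRN, EV_I_EXT = range(6)
_EV_KINDS = {
    "bg_rate": EV_BG_RATE,
    "stim_rate": EV_STIM_RATE,
    "stim_g": EV_STIM_G,
    "kappa_syn": EV_KAPPA_SYN,
    "kappa_nrn": EV_KAPPA_NRN,
    "i_ext": EV_I_EXT,
}

_NEVER = -(10 ** 15)


@njit(cache=True)
def _geom_next(s, ln1mp):
    # geometric skip sampling: next step >= s+1 with per-step hit probability p
    if ln1mp >= 0.0:  # p == 0
        return 10 ** 15
    return s + 1 + np.int64(np.log(np.random.random()) / ln1mp)


@njit(cache=True)
def _run_kernel(
    n_steps, dt, seed, rule,
    # neuron parameters
    C_m, g_L, E_L, Delta_T, V_t, V_r, b_adapt, tau_Iw, ref_steps, V_ceil,
    # neuron state
    V, Iw, refr, I_bias, I_ext, is_pyr,
    # conductance buffers, neuron-major: g[(n,4)], ring[(L,n,4)]
    g, ring, g_decay, E_rev,
    # drive
    bg_rate, stim_rate, stim_g, g_bg,
    # static synapses (CSR by presynaptic neuron)
    sp_indptr, sp_post, sp_wa, sp_wn, sp_d, sp_stp,
    # plastic synapses (CSR by presynaptic neuron; global id = CSR position)
    pp_indptr, pp_post, pp_d, p_pre, p_post,
    pq_indptr, pq_syn,
    # BCPNN state
    Za, Zn, jump_a, jump_n, dz_a, dz_n, eps,
    Pi_a, Pj_a, Pij_a, Pi_n, Pj_n, Pij_n,
    kap_syn, kap_nrn, fac_vals, K, beta_gain, wg_a, wg_n,
    wg_a_del, wg_n_del, Pbias, Pbias0, bias_on,
    # short-term plasticity
    u, x, last_spike, U, tau_A, tau_D, aug_on,
    # STDP state
    w_norm, last_pre_arr, last_post,
    lam, alpha, mu_p, mu_m, tau_plus, tau_minus, wmax_a, wmax_n,
    wmax_a_del, wmax_n_del,
    # schedule
    ev_step, ev_kind, ev_p0, ev_p1, ev_idx, ev_val,
    snap_steps, snap_wa, snap_wn, snap_bias,
    track_ids, track_every, track_w, track_tr,
    # spike recording
    spike_nrn, spike_step,
):
    np.random.seed(seed)
    n = V.shape[0]
    L = ring.shape[0]
    n_syn = p_pre.shape[0]
    n_spikes = 0
    cap = spike_nrn.shape[0]
    overflow = 0
    ev_i = 0
    snap_i = 0
    track_row = 0

    # geometric next-event clocks for background (two streams) and stimulation
    bg_ln1mp = np.zeros(n)
    stim_ln1mp = np.zeros(n)
    bg_next1 = np.empty(n, dtype=np.int64)
    bg_next2 = np.empty(n, dtype=np.int64)
    stim_next = np.empty(n, dtype=np.int64)
    for i in range(n):
        pb = bg_rate[i] * dt * 1e-3
        bg_ln1mp[i] = np.log(1.0 - pb) if pb > 0.0 else 0.0
        ps = stim_rate[i] * dt * 1e-3
        stim_ln1mp[i] = np.log(1.0 - ps) if ps > 0.0 else 0.0
        bg_next1[i] = _geom_next(-1, bg_ln1mp[i])
        bg_next2[i] = _geom_next(-1, bg_ln1mp[i])
        stim_next[i] = _geom_next(-1, stim_ln1mp[i])

    dtC = dt / C_m
    dIw = 1.0 - dt / tau_Iw

    for s in range(n_steps):
        # ---- scheduled parameter changes
        while ev_i < ev_step.shape[0] and ev_step[ev_i] <= s:
            kind = ev_kind[ev_i]
            val = ev_val[ev_i]
            for q in range(ev_p0[ev_i], ev_p1[ev_i]):
                idx = ev_idx[q]
                if kind == 0:
                    bg_rate[idx] = val
                    pb = val * dt * 1e-3
                    bg_ln1mp[idx] = np.log(1.0 - pb) if pb > 0.0 else 0.0
                    bg_next1[idx] = _geom_next(s - 1, bg_ln1mp[idx])
                    bg_next2[idx] = _geom_next(s - 1, bg_ln1mp[idx])
                elif kind == 1:
                    stim_rate[idx] = val
                    ps = val * dt * 1e-3
                    stim_ln1mp[idx] = np.log(1.0 - ps) if ps > 0.0 else 0.0
                    stim_next[idx] = _geom_next(s - 1, stim_ln1mp[idx])
                elif kind == 2:
                    stim_g[idx] = val
                elif kind == 3:
                    kap_syn[idx] = np.int8(val)
                elif kind == 4:
                    kap_nrn[idx] = np.int8(val)
                elif kind == 5:
                    I_ext[idx] = val
            ev_i += 1

        slot = s % L
        d0, d1, d2, d3 = g_decay[0], g_decay[1], g_decay[2], g_decay[3]
        E0, E1, E2, E3 = E_rev[0], E_rev[1], E_rev[2], E_rev[3]

        for i in range(n):
            # delayed deliveries arriving this step, then conductance decay
            g0 = g[i, 0] * d0 + ring[slot, i, 0]
            g1 = g[i, 1] * d1 + ring[slot, i, 1]
            g2 = g[i, 2] * d2 + ring[slot, i, 2]
            g3 = g[i, 3] * d3 + ring[slot, i, 3]
            ring[slot, i, 0] = 0.0
            ring[slot, i, 1] = 0.0
            ring[slot, i, 2] = 0.0
            ring[slot, i, 3] = 0.0

            # background noise and specific stimulation (Bernoulli events,
            # realized through exact geometric inter-event sampling)
            while bg_next1[i] <= s:
                g0 += g_bg
                bg_next1[i] = _geom_next(s, bg_ln1mp[i])
            while bg_next2[i] <= s:
                g2 += g_bg
                bg_next2[i] = _geom_next(s, bg_ln1mp[i])
            while stim_next[i] <= s:
                g0 += stim_g[i]
                stim_next[i] = _geom_next(s, stim_ln1mp[i])

            g[i, 0] = g0
            g[i, 1] = g1
            g[i, 2] = g2
            g[i, 3] = g3

            # membrane update
            Iw_i = Iw[i] * dIw
            spiked = False
            if refr[i] > 0:
                V[i] = V_r
                refr[i] -= 1
            else:
                Vi = V[i]
                I_syn = (
                    g0 * (E0 - Vi) + g1 * (E1 - Vi)
                    + g2 * (E2 - Vi) + g3 * (E3 - Vi)
                )
                arg = (Vi - V_t) / Delta_T
                if arg > 16.0:
                    arg = 16.0
                Vi += (
                    -g_L * (Vi - E_L)
                    + g_L * Delta_T * np.exp(arg)
                    - Iw_i + I_ext[i] + I_bias[i] + I_syn
                ) * dtC
                if Vi >= V_ceil:
                    spiked = True
                    Vi = V_r
                    Iw_i += b_adapt
                    refr[i] = ref_steps
                V[i] = Vi
            Iw[i] = Iw_i

            # Z traces decay every step, jump on spike
            Za[i] = eps + (Za[i] - eps) * dz_a
            Zn[i] = eps + (Zn[i] - eps) * dz_n

            if spiked:
                if n_spikes < cap:
                    spike_nrn[n_spikes] = i
                    spike_step[n_spikes] = s
                    n_spikes += 1
                else:
                    overflow = 1
                Za[i] += jump_a
                Zn[i] += jump_n

                # short-term plasticity (pyramidal-sourced synapses only)
                f_rel = 1.0
                if is_pyr[i]:
                    if last_spike[i] > _NEVER:
                        gap = (s - last_spike[i]) * dt
                        u[i] = u[i] * np.exp(-gap / tau_A)
                        x[i] = 1.0 - (1.0 - x[i]) * np.exp(-gap / tau_D)
                    x_pre = x[i]
                    if aug_on:
                        u[i] = u[i] + U * (1.0 - u[i])
                    else:
                        u[i] = U
                    x[i] = x[i] - U * x[i]
                    f_rel = u[i] * x_pre
                    last_spike[i] = s

                # static fan-out
                for k in range(sp_indptr[i], sp_indptr[i + 1]):
                    slot2 = (s + sp_d[k]) % L
                    post = sp_post[k]
                    fac = f_rel if sp_stp[k] else 1.0
                    wa = sp_wa[k] * fac
                    wn = sp_wn[k] * fac
                    if wa > 0.0:
                        ring[slot2, post, 0] += wa
                    elif wa < 0.0:
                        ring[slot2, post, 2] -= wa
                    if wn > 0.0:
                        ring[slot2, post, 1] += wn
                    elif wn < 0.0:
                        ring[slot2, post, 3] -= wn

                # plastic fan-out
                for k in range(pp_indptr[i], pp_indptr[i + 1]):
                    slot2 = (s + pp_d[k]) % L
                    post = pp_post[k]
                    if rule == 0:
                        wa = wg_a_del * np.log(Pij_a[k] / (Pi_a[k] * Pj_a[k])) * f_rel
                        wn = wg_n_del * np.log(Pij_n[k] / (Pi_n[k] * Pj_n[k])) * f_rel
                        if wa > 0.0:
                            ring[slot2, post, 0] += wa
                        elif wa < 0.0:
                            ring[slot2, post, 2] -= wa
                        if wn > 0.0:
                            ring[slot2, post, 1] += wn
                        elif wn < 0.0:
                            ring[slot2, post, 3] -= wn
                    else:
                        arrival = s + pp_d[k]
                        if last_post[k] > _NEVER:
                            dtms = (last_post[k] - arrival) * dt
                            w = w_norm[k]
                            if dtms >= 0.0:
                                w += lam * (1.0 - w) ** mu_p * np.exp(-dtms / tau_plus)
                            else:
                                w -= lam * alpha * w ** mu_m * np.exp(dtms / tau_minus)
                            if w < 0.0:
                                w = 0.0
                            elif w > 1.0:
                                w = 1.0
                            w_norm[k] = w
                        last_pre_arr[k] = arrival
                        ring[slot2, post, 0] += w_norm[k] * wmax_a_del * f_rel
                        ring[slot2, post, 1] += w_norm[k] * wmax_n_del * f_rel

                # STDP postsynaptic-side pairing
                if rule == 1:
                    for q in range(pq_indptr[i], pq_indptr[i + 1]):
                        k = pq_syn[q]
                        if last_pre_arr[k] > _NEVER:
                            dtms = (s - last_pre_arr[k]) * dt
                            w = w_norm[k]
                            if dtms >= 0.0:
                                w += lam * (1.0 - w) ** mu_p * np.exp(-dtms / tau_plus)
                            else:
                                w -= lam * alpha * w ** mu_m * np.exp(dtms / tau_minus)
                            if w < 0.0:
                                w = 0.0
                            elif w > 1.0:
                                w = 1.0
                            w_norm[k] = w
                        last_post[k] = s

        # ---- P-trace and bias relaxation on the coarse grid
        if rule == 0 and (s % K) == K - 1:
            for k in range(n_syn):
                fac = fac_vals[kap_syn[k]]
                if fac > 0.0:
                    zi = Za[p_pre[k]]
                    zj = Za[p_post[k]]
                    Pi_a[k] += (zi - Pi_a[k]) * fac
                    Pj_a[k] += (zj - Pj_a[k]) * fac
                    Pij_a[k] += (zi * zj - Pij_a[k]) * fac
                    zi = Zn[p_pre[k]]
                    zj = Zn[p_post[k]]
                    Pi_n[k] += (zi - Pi_n[k]) * fac
                    Pj_n[k] += (zj - Pj_n[k]) * fac
                    Pij_n[k] += (zi * zj - Pij_n[k]) * fac
            if bias_on:
                for i in range(n):
                    if is_pyr[i]:
                        fac = fac_vals[kap_nrn[i]]
                        if fac > 0.0:
                            # the bias trace estimates an activation
                            # probability: its drive saturates at 1 (firing
                            # above f_max cannot make a cell "more than
                            # certainly" active, so beta stays <= 0) and is
                            # floored at the consolidated prior (one task
                            # cannot erode excitability learned over long
                            # prior experience)
                            zdrive = Zn[i]
                            if zdrive > 1.0:
                                zdrive = 1.0
                            elif zdrive < Pbias0[i]:
                                zdrive = Pbias0[i]
                            pb = Pbias[i] + (zdrive - Pbias[i]) * fac
                            Pbias[i] = pb
                            I_bias[i] = beta_gain * np.log(pb)

        # ---- snapshots of every plastic weight
        if snap_i < snap_steps.shape[0] and snap_steps[snap_i] == s:
            for k in range(n_syn):
                if rule == 0:
                    snap_wa[snap_i, k] = wg_a * np.log(Pij_a[k] / (Pi_a[k] * Pj_a[k]))
                    snap_wn[snap_i, k] = wg_n * np.log(Pij_n[k] / (Pi_n[k] * Pj_n[k]))
                else:
                    snap_wa[snap_i, k] = w_norm[k] * wmax_a
                    snap_wn[snap_i, k] = w_norm[k] * wmax_n
            for i in range(n):
                snap_bias[snap_i, i] = I_bias[i]
            snap_i += 1

        # ---- continuous tracking of selected synapses
        if track_ids.shape[0] > 0 and (s % track_every) == 0:
            if track_row < track_w.shape[0]:
                for j in range(track_ids.shape[0]):
                    k = track_ids[j]
                    if rule == 0:
                        track_w[track_row, j, 0] = wg_a * np.log(
                            Pij_a[k] / (Pi_a[k] * Pj_a[k])
                        )
                        track_w[track_row, j, 1] = wg_n * np.log(
                            Pij_n[k] / (Pi_n[k] * Pj_n[k])
                        )
                        track_tr[track_row, j, 0] = Za[p_pre[k]]
                        track_tr[track_row, j, 1] = Za[p_post[k]]
                        track_tr[track_row, j, 2] = Pi_a[k]
                        track_tr[track_row, j, 3] = Pj_a[k]
                        track_tr[track_row, j, 4] = Pij_a[k]
                        track_tr[track_row, j, 5] = Zn[p_pre[k]]
                        track_tr[track_row, j, 6] = Zn[p_post[k]]
                        track_tr[track_row, j, 7] = Pi_n[k]
                        track_tr[track_row, j, 8] = Pj_n[k]
                        track_tr[track_row, j, 9] = Pij_n[k]
                    else:
                        track_w[track_row, j, 0] = w_norm[k] * wmax_a
                        track_w[track_row, j, 1] = w_norm[k] * wmax_n
                track_row += 1

    return n_spikes, overflow


@dataclass
class SimulationResult:
    """Raster, snapshots, tracked trajectories, and final plastic state."""

    dt: float
    duration: float
    spike_neurons: np.ndarray       # neuron ids
    spike_times: np.ndarray         # ms
    snapshot_times: np.ndarray      # ms
    snapshot_w_ampa: np.ndarray     # (n_snap, n_plastic) nS
    snapshot_w_nmda: np.ndarray
    snapshot_bias: np.ndarray = None  # (n_snap, n_neurons) pA
    track_times: np.ndarray = None
    track_w: np.ndarray = None      # (n_rec, n_tracked, 2) nS
    track_traces: np.ndarray = None  # (n_rec, n_tracked, 10) BCPNN traces
    final: Dict[str, np.ndarray] = field(default_factory=dict)
    overflow: bool = False

    def raster(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.spike_times, "neuron": self.spike_neurons})


class Simulator:
    """Binds a built :class:`~semnet.network.Network` to the compiled kernel.

    One instance holds the mutable plastic state, so consecutive ``run``
    calls continue the same simulation (used by multi-phase protocols).
    """

    def __init__(self, net: Network, rule: str = "bcpnn",
                 params: Optional[ModelParams] = None):
        if rule not in ("bcpnn", "stdp"):
            raise ValueError("rule must be 'bcpnn' or 'stdp'")
        self.net = net
        self.rule = RULE_BCPNN if rule == "bcpnn" else RULE_STDP
        self.params = params or net.params
        p = self.params
        self.dt = p.sim.dt
        n = net.n_neurons

        # --- neuron state
        self.V = np.full(n, p.neuron.E_L)
        self.Iw = np.zeros(n)
        self.refr = np.zeros(n, dtype=np.int64)
        self.I_bias = np.zeros(n)
        self.I_ext = np.zeros(n)
        self.is_pyr = net.is_pyr.copy()
        self.bg_rate = np.zeros(n)
        self.stim_rate = np.zeros(n)
        self.stim_g = np.full(n, p.stimulation.g_stim)

        # --- synapse tables in CSR form
        order = np.argsort(net.static_pre, kind="stable")
        sp_pre = net.static_pre[order]
        self.sp_post = net.static_post[order].astype(np.int64)
        self.sp_wa = net.static_w_ampa[order].astype(np.float64)
        self.sp_wn = net.static_w_nmda[order].astype(np.float64)
        self.sp_stp = net.static_stp[order].copy()
        sp_delay = net.static_delay[order]

        order_p = np.argsort(net.plastic_pre, kind="stable")
        self.p_pre = net.plastic_pre[order_p].astype(np.int64)
        self.p_post = net.plastic_post[order_p].astype(np.int64)
        p_delay = net.plastic_delay[order_p]
        self.plastic_order = order_p  # original-index -> CSR-position mapping

        def to_steps(d):
            return np.maximum(np.round(d / self.dt).astype(np.int64), 1)

        self.sp_d = to_steps(sp_delay)
        self.pp_d = to_steps(p_delay)
        max_d = int(max(self.sp_d.max(initial=1), self.pp_d.max(initial=1)))
        self.ring_len = max_d + 1
        self.sp_d = np.minimum(self.sp_d, self.ring_len - 1)
        self.pp_d = np.minimum(self.pp_d, self.ring_len - 1)

        self.sp_indptr = np.searchsorted(sp_pre, np.arange(n + 1)).astype(np.int64)
        self.pp_indptr = np.searchsorted(self.p_pre, np.arange(n + 1)).astype(np.int64)

        # post-side CSR over plastic synapses (STDP pairing)
        order_q = np.argsort(self.p_post, kind="stable")
        self.pq_syn = order_q.astype(np.int64)
        self.pq_indptr = np.searchsorted(
            self.p_post[order_q], np.arange(n + 1)
        ).astype(np.int64)

        # --- conductance state
        self.g = np.zeros((n, 4))
        self.ring = np.zeros((self.ring_len, n, 4))
        taus = np.asarray(p.receptors.tau_syn)
        self.g_decay = np.exp(-self.dt / taus)
        self.E_rev = np.asarray(p.receptors.E_rev, dtype=np.float64)

        # --- plasticity state
        nsyn = len(self.p_pre)
        bc = p.bcpnn
        eps = bc.epsilon
        self.Za = np.full(n, eps)
        self.Zn = np.full(n, eps)
        self.Pi_a = np.full(nsyn, eps)
        self.Pj_a = np.full(nsyn, eps)
        self.Pij_a = np.full(nsyn, eps * eps)
        self.Pi_n = np.full(nsyn, eps)
        self.Pj_n = np.full(nsyn, eps)
        self.Pij_n = np.full(nsyn, eps * eps)
        # Bias traces start at the consolidated-pattern activation prior
        # (one pattern of n_mc_per_hc active at a time): the preloaded
        # attractors come from prior learning, and that learning sets the
        # intrinsic excitability along with the weights.  A naive eps start
        # would hyperpolarize every pyramidal by ~240 pA and silence the
        # network.  Associative traces DO start at the naive prior (zero
        # initial binding); only the bias is consolidated.
        p0 = bc.bias_prior
        self.Pbias = np.full(n, p0)
        self.Pbias0 = np.full(n, p0)  # consolidated floor of the bias trace
        self.I_bias[self.is_pyr] = bc.beta_gain * np.log(p0)
        # kappa levels: index 0 frozen, 1 normal, 2 boost
        self.kappa_levels = np.array([0.0, bc.kappa, bc.kappa_boost])
        self.kap_syn = np.ones(nsyn, dtype=np.int8)
        self.kap_nrn = np.ones(n, dtype=np.int8)
        self.K = max(1, int(round(p.sim.p_update_interval / self.dt)))
        self.bias_on = self.rule == RULE_BCPNN

        self.u = np.zeros(n)
        self.x = np.ones(n)
        self.last_spike = np.full(n, _NEVER, dtype=np.int64)

        self.w_norm = np.full(nsyn, p.stdp.w0)
        self.last_pre_arr = np.full(nsyn, _NEVER, dtype=np.int64)
        self.last_post = np.full(nsyn, _NEVER, dtype=np.int64)

        self.t_offset = 0.0  # ms simulated so far

    # ------------------------------------------------------------------
    @property
    def n_plastic(self) -> int:
        return len(self.p_pre)

    def plastic_weights(self) -> Tuple[np.ndarray, np.ndarray]:
        """Current plastic weights (nS) per synapse, (fast, slow) banks."""
        bc = self.params.bcpnn
        if self.rule == RULE_BCPNN:
            wa = bc.w_gain_ampa * np.log(self.Pij_a / (self.Pi_a * self.Pj_a))
            wn = bc.w_gain_nmda * np.log(self.Pij_n / (self.Pi_n * self.Pj_n))
        else:
            wa = self.w_norm * self.params.stdp.w_max_ampa
            wn = self.w_norm * self.params.stdp.w_max_nmda
        return wa, wn

    def synapse_index(self, pre: int, post: int) -> int:
        """CSR position of the plastic synapse pre -> post (raises if absent)."""
        lo, hi = self.pp_indptr[pre], self.pp_indptr[pre + 1]
        hits = np.flatnonzero(self.p_post[lo:hi] == post)
        if len(hits) == 0:
            raise KeyError(f"no plastic synapse {pre} -> {post}")
        return int(lo + hits[0])

    def set_kappa(self, synapse_ids, level: float,
                  neuron_ids=None) -> None:
        """Immediately set the learning-rate gain for a connection subset.

        ``level`` must be one of the configured kappa levels (0, kappa_normal,
        kappa_boost).  ``neuron_ids`` additionally retargets the bias traces.
        """
        idx = self._kappa_index(level)
        self.kap_syn[np.asarray(synapse_ids, dtype=np.int64)] = idx
        if neuron_ids is not None:
            self.kap_nrn[np.asarray(neuron_ids, dtype=np.int64)] = idx

    def _kappa_index(self, level: float) -> int:
        if level < 0:
            raise ValueError("kappa must be non-negative")
        hits = np.flatnonzero(np.isclose(self.kappa_levels, level))
        if len(hits) == 0:
            raise ValueError(
                f"kappa level {level} not among configured levels "
                f"{self.kappa_levels.tolist()}"
            )
        return int(hits[0])

    # ------------------------------------------------------------------
    def run(
        self,
        duration: float,
        seed: int,
        events: Sequence[Tuple[float, str, np.ndarray, float]] = (),
        snapshot_times: Sequence[float] = (),
        track_synapses: Sequence[int] = (),
        track_interval: float = 10.0,
        spike_rate_cap: float = 80.0,
    ) -> SimulationResult:
        """Advance the simulation by ``duration`` ms.

        ``events`` is a list of (t_ms, kind, ids, value) scheduled changes;
        kinds: bg_rate, stim_rate, stim_g, kappa_syn, kappa_nrn, i_ext (for
        kappa kinds, value is the kappa *level*).  Times are relative to the
        start of this call.  ``snapshot_times`` record all plastic weights;
        ``track_synapses`` (CSR ids) are recorded every ``track_interval`` ms.
        """
        dt = self.dt
        n_steps = int(round(duration / dt))
        n = len(self.V)

        ev = sorted(events, key=lambda e: e[0])
        ev_step = np.array([int(round(e[0] / dt)) for e in ev], dtype=np.int64)
        ev_kind = np.array([_EV_KINDS[e[1]] for e in ev], dtype=np.int64)
        idx_cat: List[np.ndarray] = []
        ev_p0 = np.zeros(len(ev), dtype=np.int64)
        ev_p1 = np.zeros(len(ev), dtype=np.int64)
        ev_val = np.zeros(len(ev))
        pos = 0
        for j, (t, kind, ids, val) in enumerate(ev):
            ids = np.asarray(ids, dtype=np.int64)
            idx_cat.append(ids)
            ev_p0[j] = pos
            pos += len(ids)
            ev_p1[j] = pos
            if kind in ("kappa_syn", "kappa_nrn"):
                ev_val[j] = self._kappa_index(val)
            else:
                ev_val[j] = val
        ev_idx = (
            np.concatenate(idx_cat).astype(np.int64)
            if idx_cat else np.zeros(0, dtype=np.int64)
        )

        snap_steps = np.array(
            sorted(int(round(t / dt)) for t in snapshot_times), dtype=np.int64
        )
        snap_steps = np.minimum(snap_steps, n_steps - 1)
        snap_wa = np.zeros((len(snap_steps), self.n_plastic), dtype=np.float32)
        snap_wn = np.zeros_like(snap_wa)
        snap_bias = np.zeros((len(snap_steps), n), dtype=np.float32)

        track_ids = np.asarray(track_synapses, dtype=np.int64)
        track_every = max(1, int(round(track_interval / dt)))
        n_rec = (n_steps + track_every - 1) // track_every if len(track_ids) else 0
        track_w = np.zeros((n_rec, max(len(track_ids), 1), 2))
        track_tr = np.zeros((n_rec, max(len(track_ids), 1), 10))

        cap = int(n * duration * 1e-3 * spike_rate_cap) + 100_000
        spike_nrn = np.zeros(cap, dtype=np.int32)
        spike_step = np.zeros(cap, dtype=np.int32)

        fac_vals = -np.expm1(
            -self.kappa_levels * (self.K * dt) / self.params.bcpnn.tau_p
        )
        assoc_gain = self.params.connectivity.associative_gain
        bc = self.params.bcpnn
        npar = self.params.neuron
        stp = self.params.stp

        n_spk, overflow = _run_kernel(
            n_steps, dt, seed, self.rule,
            npar.C_m, npar.g_L, npar.E_L, npar.Delta_T, npar.V_t, npar.V_r,
            npar.b, npar.tau_Iw, int(round(npar.tau_ref / dt)), npar.V_ceil,
            self.V, self.Iw, self.refr, self.I_bias, self.I_ext, self.is_pyr,
            self.g, self.ring, self.g_decay, self.E_rev,
            self.bg_rate, self.stim_rate, self.stim_g,
            self.params.stimulation.g_bg,
            self.sp_indptr, self.sp_post, self.sp_wa, self.sp_wn, self.sp_d,
            self.sp_stp,
            self.pp_indptr, self.p_post, self.pp_d, self.p_pre, self.p_post,
            self.pq_indptr, self.pq_syn,
            self.Za, self.Zn,
            bc.z_jump(bc.tau_z_ampa), bc.z_jump(bc.tau_z_nmda),
            np.exp(-dt / bc.tau_z_ampa), np.exp(-dt / bc.tau_z_nmda), bc.epsilon,
            self.Pi_a, self.Pj_a, self.Pij_a, self.Pi_n, self.Pj_n, self.Pij_n,
            self.kap_syn, self.kap_nrn, fac_vals, self.K,
            bc.beta_gain, bc.w_gain_ampa, bc.w_gain_nmda,
            bc.w_gain_ampa * assoc_gain, bc.w_gain_nmda * assoc_gain,
            self.Pbias, self.Pbias0, self.bias_on,
            self.u, self.x, self.last_spike,
            stp.U, stp.tau_A, stp.tau_D, stp.enabled,
            self.w_norm, self.last_pre_arr, self.last_post,
            self.params.stdp.lam, self.params.stdp.alpha,
            self.params.stdp.mu_plus, self.params.stdp.mu_minus,
            self.params.stdp.tau_plus, self.params.stdp.tau_minus,
            self.params.stdp.w_max_ampa, self.params.stdp.w_max_nmda,
            self.params.stdp.w_max_ampa * assoc_gain,
            self.params.stdp.w_max_nmda * assoc_gain,
            ev_step, ev_kind, ev_p0, ev_p1, ev_idx, ev_val,
            snap_steps, snap_wa, snap_wn, snap_bias,
            track_ids, track_every, track_w, track_tr,
            spike_nrn, spike_step,
        )

        t0 = self.t_offset
        self.t_offset += duration
        # event-time state (STP clocks, STDP pairing times) carries across runs
        shift = n_steps
        self.last_spike[self.last_spike > _NEVER] -= shift
        self.last_pre_arr[self.last_pre_arr > _NEVER] -= shift
        self.last_post[self.last_post > _NEVER] -= shift

        result = SimulationResult(
            dt=dt,
            duration=duration,
            spike_neurons=spike_nrn[:n_spk].copy(),
            spike_times=spike_step[:n_spk] * dt + t0,
            snapshot_times=snap_steps * dt + t0,
            snapshot_w_ampa=snap_wa,
            snapshot_w_nmda=snap_wn,
            snapshot_bias=snap_bias,
            track_times=(np.arange(n_rec) * track_every * dt + t0
                         if n_rec else np.zeros(0)),
            track_w=track_w if len(track_ids) else None,
            track_traces=track_tr if len(track_ids) else None,
            final={
                "I_bias": self.I_bias.copy(),
                "Pbias": self.Pbias.copy(),
                "u": self.u.copy(), "x": self.x.copy(),
            },
            overflow=bool(overflow),
        )
        if overflow:
            raise RuntimeError(
                "spike buffer overflow: firing exceeded the recording cap "
                f"({spike_rate_cap} Hz/neuron average) — likely runaway activity"
            )
        return result
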