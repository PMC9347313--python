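"""Two-network architecture: layout, connectivity, preloaded attractors.

The model consists of an Item network and a Context network, each a
subsampled layer-2/3 patch of ``n_hc`` hypercolumns (HCs) with
``n_mc_per_hc`` minicolumns (MCs) of 30 pyramidal cells plus 2 basket cells
per MC.  Stored memory patterns are distributed and non-overlapping: pattern
``p`` occupies MC ``p`` of every HC of its network.

Connectivity (Bernoulli draws at the reference probabilities):

* recurrent within-HC pyramidal pairs at ``cp_pp`` and cross-HC pairs at
  ``cp_ppl`` inside each network — preloaded with static attractor weights:
  positive between same-pattern cells (within-HC stronger than cross-HC),
  negative between cells of competing MCs (a monosynaptic rendering of the
  disynaptic inhibition between attractors);
* pyramidal<->basket wiring within each HC at ``cp_pb``/``cp_bp`` with fixed
  conductances (local winner-take-all feedback inhibition);
* sparse plastic associative projections between the networks at ``cp_ppa``
  with myelinated-speed delays (these are the synapses learned during the
  episodic task, under BCPNN or STDP).

Preloaded weights are drawn in model (log-odds) units around the published
distribution means and converted to conductances through the BCPNN receptor
gains times a single scale factor, which is calibrated so that the mean
within-HC same-pattern EPSP at rest matches the 0.45 mV observable (see
:func:`calibrate_unit_scale`).

Conduction delays are distance-dependent and jittered:
``t_ij ~ N(d/V + t_min_syn, 0.3 * mean)``, truncated below at ``t_min_syn``;
all neurons of an HC share the HC center coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .params import ModelParams, LayoutParams, ConnectivityParams

ITEM, CONTEXT = 0, 1
NETWORK_NAMES = ("item", "context")


@dataclass
class PatternBook:
    """Pattern -> minicolumn assignment (identity: pattern p = MC p per HC)."""

    n_patterns: int
    layout: LayoutParams

    def __post_init__(self) -> None:
        if self.n_patterns > self.layout.n_mc_per_hc:
            raise ValueError("pattern count exceeds minicolumns per hypercolumn")

    def mc_of(self, pattern: int) -> int:
        if not 0 <= pattern < self.n_patterns:
            raise ValueError(f"unknown pattern id {pattern}")
        return pattern


@dataclass
class Network:
    """Built network: populations, synapse tables, pattern book."""

    params: ModelParams
    seed: int
    # per-neuron attribute arrays
    is_pyr: np.ndarray        # bool
    network_id: np.ndarray    # 0 = item, 1 = context
    hc: np.ndarray            # hypercolumn index within its network
    mc: np.ndarray            # minicolumn index within its HC (-1 for baskets)
    coords: np.ndarray        # (n, 2) mm, HC-center coordinates
    # static synapses (preloaded attractors + basket wiring)
    static_pre: np.ndarray
    static_post: np.ndarray
    static_w_ampa: np.ndarray   # nS, signed (negative -> GABA reversal)
    static_w_nmda: np.ndarray   # nS, signed (negative -> slow GABA reversal)
    static_delay: np.ndarray    # ms
    # plastic associative synapses (between networks)
    plastic_pre: np.ndarray
    plastic_post: np.ndarray
    plastic_delay: np.ndarray   # ms
    patterns: PatternBook = None
    unit_scale: float = 1.0     # calibrated model-unit -> nS factor
    static_stp: np.ndarray = None  # bool: short-term plasticity applies (pyr-pyr)

    # ------------------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.is_pyr)

    @property
    def n_pyr(self) -> int:
        return int(self.is_pyr.sum())

    @property
    def n_basket(self) -> int:
        return int((~self.is_pyr).sum())

    def pyr_ids(self, network: int) -> np.ndarray:
        return np.flatnonzero(self.is_pyr & (self.network_id == network))

    def pattern_cells(self, network: int, pattern: int,
                      hc: Optional[int] = None) -> np.ndarray:
        """Pyramidal ids of a pattern (optionally restricted to one HC)."""
        m = self.patterns.mc_of(pattern)
        sel = self.is_pyr & (self.network_id == network) & (self.mc == m)
        if hc is not None:
            sel &= self.hc == hc
        return np.flatnonzero(sel)

    def basket_ids(self, network: Optional[int] = None) -> np.ndarray:
        sel = ~self.is_pyr
        if network is not None:
            sel &= self.network_id == network
        return np.flatnonzero(sel)

    def static_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.static_pre, "post": self.static_post,
                "w_ampa_nS": self.static_w_ampa, "w_nmda_nS": self.static_w_nmda,
                "delay_ms": self.static_delay,
                "plastic": np.zeros(len(self.static_pre), dtype=bool),
            }
        )

    def plastic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.plastic_pre, "post": self.plastic_post,
                "w_ampa_nS": np.zeros(len(self.plastic_pre)),
                "w_nmda_nS": np.zeros(len(self.plastic_pre)),
                "delay_ms": self.plastic_delay,
                "plastic": np.ones(len(self.plastic_pre), dtype=bool),
            }
        )

    def save_tsv(self, path) -> None:
        pd.concat([self.static_table(), self.plastic_table()]).to_csv(
            path, sep="\t", index=False
        )


# ----------------------------------------------------------------------
# geometry and delays

def hc_grid(layout: LayoutParams) -> np.ndarray:
    """HC centers uniformly tiling the cortical patch, (n_hc, 2) mm."""
    w, h = layout.patch_size
    # choose a near-square tiling with nx*ny >= n_hc
    nx = int(np.ceil(np.sqrt(layout.n_hc * w / h)))
    ny = int(np.ceil(layout.n_hc / nx))
    xs = (np.arange(nx) + 0.5) * (w / nx)
    ys = (np.arange(ny) + 0.5) * (h / ny)
    pts = np.array([(x, y) for y in ys for x in xs])
    return pts[: layout.n_hc]


def sample_delay(
    distance: np.ndarray,
    speed: float,
    conn: ConnectivityParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distance-dependent conduction delays, ms.

    Mean = distance/speed + t_min_syn; SD = jitter * mean; samples truncated
    below at t_min_syn (normal draws can go negative).
    """
    if speed <= 0:
        raise ValueError("conduction speed must be positive")
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    mean = distance / speed + conn.t_min_syn
    d = rng.normal(mean, conn.delay_jitter_rel * mean)
    return np.maximum(d, conn.t_min_syn)


# ----------------------------------------------------------------------
# EPSP calibration of the model-unit -> nS scale

def _psp_peak_for_units(units: float, params: ModelParams,
                        scale: float = 1.0, stp_factor: Optional[float] = None) -> float:
    """Peak depolarization (mV) at rest for one preloaded synapse of given units.

    Uses the same measurement harness as the electrophysiology module, so the
    calibration and the later EPSP measurements share one convention (held at
    the leak reversal, first-spike release factor).
    """
    from .analysis import measure_psp

    b = params.bcpnn
    f = params.stp.U if stp_factor is None else stp_factor
    return measure_psp(
        units * b.w_gain_ampa * scale, units * b.w_gain_nmda * scale,
        params, stp_factor=f,
    )


def attractor_means(layout: LayoutParams, conn: ConnectivityParams) -> Tuple[float, float]:
    """(within-HC, cross-HC) preloaded-weight means in model units.

    Chosen so the expected-count-weighted mean over all positive attractor
    synapses equals ``attractor_mean`` with the configured within/cross ratio.
    """
    p = layout.n_pyr_per_mc
    n_loc = layout.n_hc * layout.n_mc_per_hc * p * (p - 1) * conn.cp_pp
    n_long = (
        layout.n_hc * (layout.n_hc - 1) * layout.n_mc_per_hc * p * p * conn.cp_ppl
    )
    f_loc = n_loc / (n_loc + n_long)
    m_long = conn.attractor_mean / (1.0 + f_loc * (conn.attractor_local_ratio - 1.0))
    return conn.attractor_local_ratio * m_long, m_long


def calibrate_unit_scale(params: ModelParams, target_epsp: float = 0.45) -> float:
    """Model-unit -> nS scale such that the mean within-HC EPSP is ``target_epsp``.

    The measurement convention is a single presynaptic spike with the
    first-spike short-term-plasticity release factor (u = U after its jump,
    x = 1): the response of a synapse probed from rest.  Under this
    convention the stored conductances support the regenerative ("explosive")
    attractor completion the model requires — during sustained firing the
    release factor u*x settles near U, so the effective recurrent EPSP during
    a burst stays close to the calibrated value.  The bare-conductance
    variant is available from the measurement harness for comparison.
    Sub-millivolt PSPs are linear in the conductance to well under a percent,
    so a single reference simulation fixes the scale; the returned value is
    refined with one secant step to absorb the residual nonlinearity.
    """
    m_loc, _ = attractor_means(params.layout, params.connectivity)
    peak1 = _psp_peak_for_units(m_loc, params, scale=1.0)
    scale = target_epsp / peak1
    peak2 = _psp_peak_for_units(m_loc, params, scale=scale)
    if peak2 > 0:
        scale *= target_epsp / peak2
    return float(scale)


# ----------------------------------------------------------------------
# builder

def _draw_block(rng, pre_ids, post_ids, p, exclude_diag=False):
    """Bernoulli connectivity between two id arrays; returns (pre, post) indices."""
    mask = rng.random((len(pre_ids), len(post_ids))) < p
    if exclude_diag:
        np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(mask)
    return pre_ids[ii], post_ids[jj]


def build_network(
    params: Optional[ModelParams] = None,
    seed: int = 0,
    calibrate: bool = True,
    unit_scale: Optional[float] = None,
) -> Network:
    """Construct the two-network model for a fixed seed.

    Identical seeds yield identical synapse tables.  ``unit_scale`` overrides
    the EPSP calibration (useful to reuse a scale across seeds: the
    calibration is deterministic given parameters, so this is purely a
    time saver).
    """
    params = params or ModelParams()
    lay, conn = params.layout, params.connectivity
    rng = np.random.default_rng(seed)

    if unit_scale is None:
        unit_scale = calibrate_unit_scale(params) if calibrate else conn.unit_scale

    n_pyr_net = lay.n_pyr_per_network
    n_bask_net = lay.n_basket_per_network
    n_total = 2 * (n_pyr_net + n_bask_net)

    is_pyr = np.zeros(n_total, dtype=bool)
    network_id = np.zeros(n_total, dtype=np.int32)
    hc_arr = np.zeros(n_total, dtype=np.int32)
    mc_arr = np.full(n_total, -1, dtype=np.int32)
    coords = np.zeros((n_total, 2))

    grid = hc_grid(lay)
    n_baskets_per_hc = lay.n_mc_per_hc * lay.n_basket_per_mc

    # layout: for each network, all pyramidals (HC-major, MC-minor), then baskets
    def net_offsets(net):
        base = net * (n_pyr_net + n_bask_net)
        return base, base + n_pyr_net  # pyr base, basket base

    for net in (ITEM, CONTEXT):
        pyr0, bask0 = net_offsets(net)
        offset = np.array([net * lay.internetwork_distance, 0.0])
        for h in range(lay.n_hc):
            for m in range(lay.n_mc_per_hc):
                i0 = pyr0 + (h * lay.n_mc_per_hc + m) * lay.n_pyr_per_mc
                sl = slice(i0, i0 + lay.n_pyr_per_mc)
                is_pyr[sl] = True
                network_id[sl] = net
                hc_arr[sl] = h
                mc_arr[sl] = m
                coords[sl] = grid[h] + offset
            b0 = bask0 + h * n_baskets_per_hc
            sl = slice(b0, b0 + n_baskets_per_hc)
            network_id[sl] = net
            hc_arr[sl] = h
            coords[sl] = grid[h] + offset

    # ------------------------------------------------------------------
    # static recurrent synapses (preloaded attractors + competition)
    m_loc, m_long = attractor_means(lay, conn)
    cv = conn.attractor_cv
    b = params.bcpnn
    ga, gn = b.w_gain_ampa * unit_scale, b.w_gain_nmda * unit_scale

    pre_l, post_l, units_l, delay_l = [], [], [], []

    def pyr_ids_of_hc(net, h):
        pyr0, _ = net_offsets(net)
        i0 = pyr0 + h * lay.n_mc_per_hc * lay.n_pyr_per_mc
        return np.arange(i0, i0 + lay.n_mc_per_hc * lay.n_pyr_per_mc)

    for net in (ITEM, CONTEXT):
        for ha in range(lay.n_hc):
            ids_a = pyr_ids_of_hc(net, ha)
            for hb in range(lay.n_hc):
                ids_b = pyr_ids_of_hc(net, hb)
                p = conn.cp_pp if ha == hb else conn.cp_ppl
                pre, post = _draw_block(rng, ids_a, ids_b, p, exclude_diag=ha == hb)
                if len(pre) == 0:
                    continue
                same = mc_arr[pre] == mc_arr[post]
                mu_pos = m_loc if ha == hb else m_long
                units = np.where(
                    same,
                    np.maximum(rng.normal(mu_pos, cv * mu_pos, len(pre)), 0.05 * mu_pos),
                    np.minimum(
                        rng.normal(conn.competing_mean,
                                   cv * abs(conn.competing_mean), len(pre)),
                        0.05 * conn.competing_mean,
                    ),
                )
                dist = float(np.linalg.norm(grid[ha] - grid[hb]))
                delays = sample_delay(
                    np.full(len(pre), dist), conn.speed, conn, rng
                )
                pre_l.append(pre)
                post_l.append(post)
                units_l.append(units)
                delay_l.append(delays)

    static_pre = np.concatenate(pre_l)
    static_post = np.concatenate(post_l)
    units = np.concatenate(units_l)
    static_delay = np.concatenate(delay_l)
    static_w_ampa = units * ga * conn.recurrent_gain
    static_w_nmda = units * gn * conn.recurrent_gain

    # basket wiring within each HC (static conductances, no NMDA component)
    bp_pre, bp_post, bp_wa, bp_delay = [], [], [], []
    for net in (ITEM, CONTEXT):
        _, bask0 = net_offsets(net)
        for h in range(lay.n_hc):
            pyr = pyr_ids_of_hc(net, h)
            bask = np.arange(bask0 + h * n_baskets_per_hc,
                             bask0 + (h + 1) * n_baskets_per_hc)
            pre, post = _draw_block(rng, pyr, bask, conn.cp_pb)
            bp_pre.append(pre); bp_post.append(post)
            bp_wa.append(np.full(len(pre), conn.g_pb))
            bp_delay.append(sample_delay(np.zeros(len(pre)), conn.speed, conn, rng))
            pre, post = _draw_block(rng, bask, pyr, conn.cp_bp)
            bp_pre.append(pre); bp_post.append(post)
            bp_wa.append(np.full(len(pre), conn.g_bp))
            bp_delay.append(sample_delay(np.zeros(len(pre)), conn.speed, conn, rng))

    n_rec = len(static_pre)
    static_pre = np.concatenate([static_pre] + bp_pre)
    static_post = np.concatenate([static_post] + bp_post)
    static_w_ampa = np.concatenate([static_w_ampa] + bp_wa)
    static_w_nmda = np.concatenate([static_w_nmda] + [np.zeros(len(x)) for x in bp_wa])
    static_delay = np.concatenate([static_delay] + bp_delay)
    # short-term plasticity acts on every pyramidal-sourced (glutamatergic)
    # synapse, including the drive onto basket cells; basket-sourced GABAergic
    # synapses are static
    static_stp = np.concatenate(
        [np.ones(n_rec, dtype=bool)]
        + [is_pyr[x].astype(bool) for x in bp_pre]
    )

    # ------------------------------------------------------------------
    # plastic associative synapses between the networks (both directions)
    pl_pre, pl_post, pl_delay = [], [], []
    for net_a, net_b in ((ITEM, CONTEXT), (CONTEXT, ITEM)):
        for ha in range(lay.n_hc):
            ids_a = pyr_ids_of_hc(net_a, ha)
            ca = grid[ha] + np.array([net_a * lay.internetwork_distance, 0.0])
            for hb in range(lay.n_hc):
                ids_b = pyr_ids_of_hc(net_b, hb)
                cb = grid[hb] + np.array([net_b * lay.internetwork_distance, 0.0])
                pre, post = _draw_block(rng, ids_a, ids_b, conn.cp_ppa)
                if len(pre) == 0:
                    continue
                dist = float(np.linalg.norm(ca - cb))
                pl_pre.append(pre)
                pl_post.append(post)
                pl_delay.append(
                    sample_delay(np.full(len(pre), dist), conn.speed_myelinated,
                                 conn, rng)
                )

    patterns = PatternBook(n_patterns=lay.n_mc_per_hc, layout=lay)

    return Network(
        params=replace(params,
                       connectivity=replace(conn, unit_scale=unit_scale)),
        seed=seed,
        is_pyr=is_pyr, network_id=network_id, hc=hc_arr, mc=mc_arr, coords=coords,
        static_pre=static_pre.astype(np.int64),
        static_post=static_post.astype(np.int64),
        static_w_ampa=static_w_ampa.astype(np.float64),
        static_w_nmda=static_w_nmda.astype(np.float64),
        static_delay=static_delay.astype(np.float64),
        static_stp=static_stp,
        plastic_pre=np.concatenate(pl_pre).astype(np.int64),
        plastic_post=np.concatenate(pl_post).astype(np.int64),
        plastic_delay=np.concatenate(pl_delay).astype(np.float64),
        patterns=patterns,
        unit_scale=float(unit_scale),
    )


def expected_same_pattern_fan_in(params: ModelParams) -> float:
    """Analytic expected plastic + recurrent same-selectivity fan-in per cell."""
    lay, conn = params.layout, params.connectivity
    p = lay.n_pyr_per_mc
    return (
        (p - 1) * conn.cp_pp
        + (lay.n_hc - 1) * p * conn.cp_ppl
        + lay.n_hc * p * conn.cp_ppa
    )
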