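"""Attractor-activation detection, recall scoring, and PSP measurements.

Detection follows the population-rate approach: the spike train of a
pattern-selective population (one minicolumn of 30 cells in a designated
sample hypercolumn) is filtered with an exponential moving average (EMA)
whose steady state equals the per-neuron firing rate, and activations are
threshold crossings at ``r_th`` with hysteresis — sub-threshold dips shorter
than the re-cross guard do not terminate an event, and events shorter than
the minimal duration are discarded.

The printed recursion of the source model multiplies the *previous* estimate
by dT/tau, which discards 97.5% of the state per millisecond and cannot
implement an EMA with a 40 ms time constant; the standard leaky form

    e_t = (1 - dT/tau) * e_{t-dT} + (spike count)_t / (tau * n_pop)

is used instead (in Hz with tau in seconds), and the literal form is kept
behind ``DetectorParams.literal_recursion`` for comparison.

Recall scoring maps detector output to the Remember/Know vocabulary: an item
cue that reactivates its item attractor *and* at least one associated
context within the response window scores remember-like; item-only
activation scores know-like; neither is a miss.  Context cues are scored
symmetrically with the associated item as target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_dynamics import holding_current, simulate_voltage
from .params import DetectorParams, ModelParams
from .network import Network


@dataclass
class AttractorEvent:
    """One detected attractor activation."""

    pattern: int
    network: int
    onset: float    # ms
    offset: float   # ms
    peak_rate: float  # Hz

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def ema_rate(
    spike_times: np.ndarray,
    spike_neurons: np.ndarray,
    population: np.ndarray,
    duration: float,
    params: DetectorParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """Leaky population-rate estimate, Hz, sampled every ``params.dT`` ms.

    Calibrated so a constant per-neuron rate f yields a steady state of f:
    each spike contributes dT-binned counts scaled by 1/(tau * n_pop) with
    tau in seconds, against a per-step decay of (1 - dT/tau).
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    sel = np.isin(spike_neurons, population)
    ts = spike_times[sel]
    n_bins = int(np.ceil(duration / params.dT)) + 1
    counts = np.bincount(
        np.clip((ts / params.dT).astype(int), 0, n_bins - 1), minlength=n_bins
    )
    n_pop = len(population)
    tau_s = params.tau * 1e-3
    if params.literal_recursion:
        decay = params.dT / params.tau
    else:
        decay = 1.0 - params.dT / params.tau
    gain = 1.0 / (tau_s * n_pop)
    e = np.empty(n_bins)
    acc = 0.0
    for k in range(n_bins):
        acc = acc * decay + counts[k] * gain
        e[k] = acc
    t = np.arange(n_bins) * params.dT
    return t, e


def detect_events(
    t: np.ndarray,
    rate: np.ndarray,
    params: DetectorParams,
    pattern: int = -1,
    network: int = -1,
) -> List[AttractorEvent]:
    """Threshold detection with offset hysteresis on a uniformly sampled series.

    An activation terminates only if the rate stays below threshold for the
    full re-cross guard; activations shorter than the minimal duration are
    discarded.  Deterministic and independent of how the series was chunked.
    """
    above = rate >= params.r_th
    events: List[AttractorEvent] = []
    dT = params.dT
    guard = int(round(params.recross_guard / dT))
    i = 0
    n = len(rate)
    while i < n:
        if above[i]:
            onset = i
            j = i
            while j < n:
                if above[j]:
                    j += 1
                else:
                    # below threshold: terminate only if no re-cross within guard
                    k_end = min(j + guard, n)
                    nxt = -1
                    for k in range(j, k_end):
                        if above[k]:
                            nxt = k
                            break
                    if nxt < 0:
                        break
                    j = nxt
            offset = j
            if (offset - onset) * dT >= params.min_duration:
                events.append(
                    AttractorEvent(
                        pattern=pattern,
                        network=network,
                        onset=float(t[onset]),
                        offset=float(t[min(offset, n - 1)]),
                        peak_rate=float(rate[onset:offset].max()),
                    )
                )
            i = offset + 1
        else:
            i += 1
    return events


def detect_pattern_events(
    net: Network,
    spike_times: np.ndarray,
    spike_neurons: np.ndarray,
    duration: float,
    params: Optional[DetectorParams] = None,
) -> List[AttractorEvent]:
    """Run the detector for every pattern of both networks (sample-HC MCs)."""
    params = params or net.params.detector
    out: List[AttractorEvent] = []
    for network in (0, 1):
        for pat in range(net.patterns.n_patterns):
            pop = net.pattern_cells(network, pat, hc=params.sample_hc)
            t, e = ema_rate(spike_times, spike_neurons, pop, duration, params)
            out.extend(detect_events(t, e, params, pattern=pat, network=network))
    return out


def score_recall(
    events: Sequence[AttractorEvent],
    cue_pattern: int,
    cue_network: int,
    associates: Sequence[int],
    window: Tuple[float, float],
) -> str:
    """Score one cue: 'remember', 'know', or 'miss'.

    ``associates`` are the pattern ids paired with the cued pattern in the
    *other* network.  An event counts if its onset falls inside the response
    window.  For an item cue, the item attractor must reactivate for any
    response; the cue's own 50 ms external drive alone rarely satisfies the
    detector's minimal duration, so this is a genuine attractor criterion.
    """
    t0, t1 = window
    if cue_network not in (0, 1):
        raise ValueError("cue_network must be 0 (item) or 1 (context)")

    def hit(ev: AttractorEvent, network: int, patterns: Sequence[int]) -> bool:
        return (
            ev.network == network
            and ev.pattern in patterns
            and t0 <= ev.onset < t1
        )

    target_self = any(hit(ev, cue_network, [cue_pattern]) for ev in events)
    target_assoc = any(hit(ev, 1 - cue_network, associates) for ev in events)
    if target_self and target_assoc:
        return "remember"
    if target_self:
        return "know"
    return "miss"


# ----------------------------------------------------------------------
# electrophysiology harness

def measure_psp(
    w_ampa: float,
    w_nmda: float,
    params: ModelParams,
    holding_V: Optional[float] = None,
    stp_factor: float = 1.0,
    dt: float = 0.01,
    duration: float = 300.0,
) -> float:
    """Peak membrane deflection (mV, signed) from a single presynaptic spike.

    The postsynaptic cell is held at ``holding_V`` (default: leak reversal)
    by a constant current; one spike is delivered through the given
    conductances (negative weights are routed to the inhibitory reversal with
    their bank's kinetics, as in the network).  Background noise is off and
    plasticity frozen by construction.  ``stp_factor`` optionally applies a
    short-term-plasticity release scaling; 1.0 measures the bare conductance.
    """
    V_hold = params.neuron.E_L if holding_V is None else holding_V
    I_hold = holding_current(V_hold, params.neuron)
    events: Dict[int, list] = {0: [], 1: [], 2: [], 3: []}
    t_on = 50.0
    wa, wn = w_ampa * stp_factor, w_nmda * stp_factor
    if wa >= 0:
        events[0].append((t_on, wa))
    else:
        events[2].append((t_on, -wa))
    if wn >= 0:
        events[1].append((t_on, wn))
    else:
        events[3].append((t_on, -wn))
    t, V, _ = simulate_voltage(
        params.neuron, params.receptors, duration, dt, events,
        I_ext=I_hold, V0=V_hold,
    )
    sl = t >= t_on
    dev = V[sl] - V_hold
    return float(dev[np.argmax(np.abs(dev))])


def psp_analytic_peak(
    g: float, tau_syn: float, E_syn: float, V_hold: float, params
) -> float:
    """Closed-form peak of the linearized passive PSP (double exponential).

    Treats the membrane as a passive RC with time constant tau_m = C_m/g_L
    and a fixed driving force at the holding potential — the textbook
    small-signal oracle the simulated PSP is checked against.
    """
    tau_m = params.C_m / params.g_L
    a, bq = 1.0 / tau_syn, 1.0 / tau_m
    if np.isclose(a, bq):
        t_pk = tau_syn
        shape = t_pk * np.exp(-a * t_pk)
    else:
        t_pk = np.log(a / bq) / (a - bq)
        shape = (np.exp(-bq * t_pk) - np.exp(-a * t_pk)) / (a - bq)
    return g * (E_syn - V_hold) / params.C_m * shape


def measure_connection_psps(
    net: Network,
    pre_ids: np.ndarray,
    post_ids: np.ndarray,
    w_ampa: np.ndarray,
    w_nmda: np.ndarray,
    holding_V: Optional[float] = None,
    stp_factor: float = 1.0,
    max_n: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """PSP distribution over a sample of explicit connections.

    Returns a frame (pre, post, w_ampa, w_nmda, psp_mV).  Unconnected pairs
    never enter: callers pass existing synapse arrays.
    """
    n = len(pre_ids)
    if n > max_n:
        rng = rng or np.random.default_rng(0)
        sel = rng.choice(n, size=max_n, replace=False)
    else:
        sel = np.arange(n)
    rows = []
    for k in sel:
        peak = measure_psp(
            float(w_ampa[k]), float(w_nmda[k]), net.params,
            holding_V=holding_V, stp_factor=stp_factor,
        )
        rows.append((int(pre_ids[k]), int(post_ids[k]),
                     float(w_ampa[k]), float(w_nmda[k]), peak))
    return pd.DataFrame(rows, columns=["pre", "post", "w_ampa", "w_nmda", "psp_mV"])


def within_hc_same_pattern_epsp(
    net: Network, max_n: int = 200, stp_factor: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """EPSPs of preloaded within-HC same-pattern connections at rest.

    By default uses the first-spike release factor (u = U after its jump,
    x = 1), the convention of the preload calibration; pass
    ``stp_factor=1.0`` for the bare-conductance variant.
    """
    pre, post = net.static_pre, net.static_post
    sel = (
        net.is_pyr[pre] & net.is_pyr[post]
        & (net.network_id[pre] == net.network_id[post])
        & (net.hc[pre] == net.hc[post])
        & (net.mc[pre] == net.mc[post])
        & (net.mc[pre] >= 0)
    )
    idx = np.flatnonzero(sel)
    f = net.params.stp.U if stp_factor is None else stp_factor
    return measure_connection_psps(
        net, pre[idx], post[idx],
        net.static_w_ampa[idx] / net.params.connectivity.recurrent_gain,
        net.static_w_nmda[idx] / net.params.connectivity.recurrent_gain,
        stp_factor=f, max_n=max_n, rng=rng,
    )


def unitary_ipsp(params: Optional[ModelParams] = None, holding_V: float = -60.0) -> float:
    """Peak deflection of a single basket->pyramidal spike at the holding potential."""
    params = params or ModelParams()
    return measure_psp(params.connectivity.g_bp, 0.0, params, holding_V=holding_V)


def summarize_distributions(
    weights_by_count: Dict[int, np.ndarray],
) -> pd.DataFrame:
    """Mean/SD/quantiles of weight (or PSP) samples keyed by association count."""
    rows = []
    for count in sorted(weights_by_count):
        w = np.asarray(weights_by_count[count], dtype=float)
        if len(w) == 0:
            continue
        rows.append(
            (count, len(w), w.mean(), w.std(),
             np.percentile(w, 25), np.percentile(w, 50), np.percentile(w, 75))
        )
    return pd.DataFrame(
        rows, columns=["n_assoc", "n", "mean", "sd", "q25", "median", "q75"]
    )
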