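"""Episodic item-context task: schedules, trials, and experiments.

The task binds item patterns (Item network) to context patterns (Context
network) through the plastic associative pathway.  A trial is:

1. a noise-only settling period (avoids initialization transients);
2. the encoding phase: one 250 ms epoch per item-context pairing with a
   500 ms interstimulus interval, both patterns driven at 500 Hz / +1.5 nS
   (pairing order shuffled per trial by default);
3. a 1 s delay (background switches to the recall rate at its start);
4. the test phase: brief 50 ms / 400 Hz cues of items (variant A) or
   contexts (variant B), one scoring window per cue.

The default association map follows the reference task: four items forming
3, 2, 1 and 4 context associations respectively, over ten distinct contexts,
each context used exactly once (letters A..J map to context patterns 0..9;
item-1 pairs with contexts A, E, J).

Variants:

* ``item-cued`` / ``context-cued`` — the two basic recall directions;
* ``multi-cue`` — context-cued, but every context of the highest-association
  item is cued in sequence and scored in one window (evidence accumulation);
* ``preferential-retention`` — item-cued with the learning rate transiently
  raised (kappa_boost) for one designated pairing during its encoding epoch
  only, on the associative synapses of that pairing (both directions) and
  the bias traces of the paired cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Simulator
from .network import Network, ITEM, CONTEXT
from .params import ModelParams
from . import analysis

DEFAULT_ASSOCIATION_MAP: Dict[int, Tuple[int, ...]] = {
    0: (0, 4, 9),     # item-1: contexts A, E, J (3 associations)
    1: (1, 5),        # item-2: 2 associations
    2: (2,),          # item-3: 1 association
    3: (3, 6, 7, 8),  # item-4: 4 associations
}

VARIANTS = ("item-cued", "context-cued", "multi-cue", "preferential-retention")


@dataclass
class StimulusEpoch:
    """One timed Poisson-drive epoch onto one pattern."""

    phase: str          # encoding | cue
    network: int        # 0 item, 1 context
    pattern: int
    onset: float        # ms
    duration: float     # ms
    rate: float         # Hz
    conductance: float  # nS


@dataclass
class CueSpec:
    """Scoring unit: one cue (or cue burst) and its response window."""

    network: int
    pattern: int
    associates: Tuple[int, ...]
    n_assoc: int
    window: Tuple[float, float]


@dataclass
class StimulusSchedule:
    epochs: List[StimulusEpoch]
    cues: List[CueSpec]
    pairings: List[Tuple[int, int, float, float]]  # (item, ctx, onset, offset)
    t_encoding_end: float
    t_test_start: float
    duration: float


@dataclass
class ExperimentConfig:
    variant: str = "item-cued"
    rule: str = "bcpnn"
    association_map: Dict[int, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ASSOCIATION_MAP)
    )
    n_trials: int = 20
    shuffle_encoding: bool = True
    freeze_at_recall: bool = False   # kappa -> 0 during the test phase
    boost_pairing: Tuple[int, int] = (0, 4)  # (item, context) for kappa_boost
    kappa_boost: Optional[float] = None      # defaults to params.bcpnn.kappa_boost
    stim_rate_factor: float = 1.0    # compensation hooks (augmentation removal)
    stim_g_factor: float = 1.0
    multi_cue_spacing: float = 100.0  # ms between sequential cues (multi-cue)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        used = [c for ctxs in self.association_map.values() for c in ctxs]
        if len(used) != len(set(used)):
            raise ValueError("each context may be associated with at most one item")

    def pairings(self) -> List[Tuple[int, int]]:
        return [(i, c) for i, ctxs in sorted(self.association_map.items())
                for c in ctxs]

    def n_assoc(self, item: int) -> int:
        return len(self.association_map[item])


@dataclass
class TrialResult:
    """Raster, detector output, per-cue outcomes, and weight/bias snapshots."""

    config: ExperimentConfig
    seed: int
    schedule: StimulusSchedule
    spike_times: np.ndarray
    spike_neurons: np.ndarray
    events: List[analysis.AttractorEvent]
    outcomes: pd.DataFrame     # cue, network, pattern, n_assoc, outcome, recalled
    snapshots: Dict[str, Tuple[np.ndarray, np.ndarray]]  # phase -> (w_fast, w_slow)
    bias_snapshots: Dict[str, np.ndarray]  # phase -> per-neuron bias current, pA
    bias_final: np.ndarray     # per-neuron intrinsic-excitability current, pA


def build_schedule(
    config: ExperimentConfig,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
) -> StimulusSchedule:
    """Lay out encoding epochs, delay, and cue windows for one trial."""
    st = params.stimulation
    n_pat = params.layout.n_mc_per_hc
    for item, ctxs in config.association_map.items():
        if item >= n_pat or any(c >= n_pat for c in ctxs):
            raise ValueError("association map references unknown patterns")

    pairings = config.pairings()
    if config.shuffle_encoding:
        rng = rng or np.random.default_rng(0)
        order = rng.permutation(len(pairings))
        pairings = [pairings[k] for k in order]

    r_stim = st.r_stim * config.stim_rate_factor
    r_cue = st.r_cue * config.stim_rate_factor
    g_stim = st.g_stim * config.stim_g_factor

    epochs: List[StimulusEpoch] = []
    pairing_times: List[Tuple[int, int, float, float]] = []
    t = st.t_settle
    for item, ctx in pairings:
        epochs.append(StimulusEpoch("encoding", ITEM, item, t, st.t_stim,
                                    r_stim, g_stim))
        epochs.append(StimulusEpoch("encoding", CONTEXT, ctx, t, st.t_stim,
                                    r_stim, g_stim))
        pairing_times.append((item, ctx, t, t + st.t_stim))
        t += st.t_stim + st.isi
    t_encoding_end = t - st.isi + 0.0  # end of the last stimulus
    t_test = t_encoding_end + st.t_delay

    cues: List[CueSpec] = []
    tc = t_test
    items = sorted(config.association_map)
    if config.variant in ("item-cued", "preferential-retention"):
        for item in items:
            epochs.append(StimulusEpoch("cue", ITEM, item, tc, st.t_cue,
                                        r_cue, g_stim))
            cues.append(CueSpec(ITEM, item, tuple(config.association_map[item]),
                                config.n_assoc(item), (tc, tc + st.cue_window)))
            tc += st.cue_window
    elif config.variant == "context-cued":
        for item in items:
            for ctx in config.association_map[item]:
                epochs.append(StimulusEpoch("cue", CONTEXT, ctx, tc, st.t_cue,
                                            r_cue, g_stim))
                cues.append(CueSpec(CONTEXT, ctx, (item,), config.n_assoc(item),
                                    (tc, tc + st.cue_window)))
                tc += st.cue_window
    elif config.variant == "multi-cue":
        max_item = max(items, key=config.n_assoc)
        for item in items:
            ctxs = config.association_map[item]
            if item == max_item:
                # cue all associated contexts sequentially, one scoring window
                t0 = tc
                for k, ctx in enumerate(ctxs):
                    epochs.append(
                        StimulusEpoch("cue", CONTEXT, ctx,
                                      tc + k * config.multi_cue_spacing,
                                      st.t_cue, r_cue, g_stim)
                    )
                t_last = tc + (len(ctxs) - 1) * config.multi_cue_spacing
                cues.append(CueSpec(CONTEXT, ctxs[0], (item,), config.n_assoc(item),
                                    (t0, t_last + st.cue_window)))
                tc = t_last + st.cue_window
            else:
                ctx = ctxs[0]
                epochs.append(StimulusEpoch("cue", CONTEXT, ctx, tc, st.t_cue,
                                            r_cue, g_stim))
                cues.append(CueSpec(CONTEXT, ctx, (item,), config.n_assoc(item),
                                    (tc, tc + st.cue_window)))
                tc += st.cue_window

    duration = tc + 100.0
    return StimulusSchedule(
        epochs=epochs, cues=cues, pairings=pairing_times,
        t_encoding_end=t_encoding_end, t_test_start=t_test, duration=duration,
    )


# ----------------------------------------------------------------------

def associative_synapses(
    sim: Simulator, net: Network, item: int, ctx: int,
    direction: str = "both",
) -> np.ndarray:
    """CSR ids of plastic synapses between an item pattern and a context pattern."""
    item_cells = np.zeros(net.n_neurons, dtype=bool)
    item_cells[net.pattern_cells(ITEM, item)] = True
    ctx_cells = np.zeros(net.n_neurons, dtype=bool)
    ctx_cells[net.pattern_cells(CONTEXT, ctx)] = True
    fwd = item_cells[sim.p_pre] & ctx_cells[sim.p_post]
    bwd = ctx_cells[sim.p_pre] & item_cells[sim.p_post]
    if direction == "fwd":
        sel = fwd
    elif direction == "bwd":
        sel = bwd
    elif direction == "both":
        sel = fwd | bwd
    else:
        raise ValueError("direction must be fwd, bwd, or both")
    return np.flatnonzero(sel)


def toggle_augmentation(
    params: ModelParams, enabled: bool,
    compensate: bool = False,
    rate_factor: float = 1.3, g_factor: float = 1.2,
) -> Tuple[ModelParams, ExperimentConfig]:
    """Enable/disable synaptic augmentation, optionally with drive compensation.

    With augmentation disabled, the utilization u is pinned to U on every
    spike (no facilitation accumulates).  Compensation raises stimulation
    rates and the stimulus conductance to elicit comparable spiking activity;
    the returned factors live in the ExperimentConfig so schedules pick
    them up.
    """
    new = replace(params, stp=replace(params.stp, enabled=enabled))
    cfg = ExperimentConfig(
        stim_rate_factor=rate_factor if (compensate and not enabled) else 1.0,
        stim_g_factor=g_factor if (compensate and not enabled) else 1.0,
    )
    return new, cfg


def run_trial(
    net: Network,
    config: ExperimentConfig,
    seed: int,
    params: Optional[ModelParams] = None,
    keep_raster: bool = True,
) -> TrialResult:
    """Simulate one full trial (settle, encoding, delay, cued test).

    Bit-reproducible for a fixed seed.  Returns detector events, per-cue
    Remember/Know/miss outcomes, and weight snapshots taken at the end of
    encoding and at the end of the trial.
    """
    params = params or net.params
    rng = np.random.default_rng(seed)
    schedule = build_schedule(config, params, rng)
    sim = Simulator(net, config.rule, params=params)
    st = params.stimulation

    pyr = np.flatnonzero(net.is_pyr)
    bask = net.basket_ids()
    bgf = 1.0 if st.bg_per_generator else 0.5  # rate per generator of the pair
    events: List[Tuple[float, str, np.ndarray, float]] = [
        (0.0, "bg_rate", pyr, st.bg_rate_pyr_encoding * bgf),
        (0.0, "bg_rate", bask, st.bg_rate_basket * bgf),
        (schedule.t_encoding_end, "bg_rate", pyr, st.bg_rate_pyr_recall * bgf),
    ]
    for ep in schedule.epochs:
        cells = net.pattern_cells(ep.network, ep.pattern)
        events.append((ep.onset, "stim_g", cells, ep.conductance))
        events.append((ep.onset, "stim_rate", cells, ep.rate))
        events.append((ep.onset + ep.duration, "stim_rate", cells, 0.0))

    if config.variant == "preferential-retention":
        item_b, ctx_b = config.boost_pairing
        if ctx_b not in config.association_map.get(item_b, ()):
            raise ValueError("boost_pairing must be one of the encoded pairings")
        kb = (params.bcpnn.kappa_boost if config.kappa_boost is None
              else config.kappa_boost)
        syn = associative_synapses(sim, net, item_b, ctx_b, "both")
        cells = np.concatenate([
            net.pattern_cells(ITEM, item_b), net.pattern_cells(CONTEXT, ctx_b)
        ])
        for item, ctx, t0, t1 in schedule.pairings:
            if (item, ctx) == (item_b, ctx_b):
                events.append((t0, "kappa_syn", syn, kb))
                events.append((t0, "kappa_nrn", cells, kb))
                events.append((t1, "kappa_syn", syn, params.bcpnn.kappa))
                events.append((t1, "kappa_nrn", cells, params.bcpnn.kappa))

    if config.freeze_at_recall:
        all_syn = np.arange(sim.n_plastic)
        events.append((schedule.t_test_start, "kappa_syn", all_syn, 0.0))
        events.append((schedule.t_test_start, "kappa_nrn", pyr, 0.0))

    res = sim.run(
        schedule.duration,
        seed=seed,
        events=events,
        snapshot_times=[schedule.t_encoding_end, schedule.duration - 1.0],
    )

    detected = analysis.detect_pattern_events(
        net, res.spike_times, res.spike_neurons, schedule.duration,
        params.detector,
    )

    rows = []
    for k, cue in enumerate(schedule.cues):
        outcome = analysis.score_recall(
            detected, cue.pattern, cue.network, cue.associates, cue.window
        )
        recalled = sorted(
            {ev.pattern for ev in detected
             if ev.network == 1 - cue.network and ev.pattern in cue.associates
             and cue.window[0] <= ev.onset < cue.window[1]}
        )
        rows.append((k, cue.network, cue.pattern, cue.n_assoc, outcome,
                     ",".join(map(str, recalled))))
    outcomes = pd.DataFrame(
        rows, columns=["cue", "network", "pattern", "n_assoc", "outcome",
                       "recalled"],
    )

    return TrialResult(
        config=config,
        seed=seed,
        schedule=schedule,
        spike_times=res.spike_times if keep_raster else np.zeros(0),
        spike_neurons=res.spike_neurons if keep_raster else np.zeros(0, int),
        events=detected,
        outcomes=outcomes,
        snapshots={
            "post_encoding": (res.snapshot_w_ampa[0], res.snapshot_w_nmda[0]),
            "end": (res.snapshot_w_ampa[1], res.snapshot_w_nmda[1]),
        },
        bias_snapshots={
            "post_encoding": res.snapshot_bias[0],
            "end": res.snapshot_bias[1],
        },
        bias_final=res.final["I_bias"],
    )


def associative_weight_table(
    net: Network, sim_or_trial, config: ExperimentConfig,
    snapshot: str = "post_encoding",
) -> pd.DataFrame:
    """Per-synapse weights of every encoded pairing, tagged by association count.

    Returns a tidy frame (item, ctx, n_assoc, direction, w_fast, w_slow) over
    the plastic synapses that link each encoded item-context pair, taken from
    a TrialResult snapshot.
    """
    trial: TrialResult = sim_or_trial
    wa, wn = trial.snapshots[snapshot]
    # rebuild the CSR ordering exactly as the Simulator does
    order_p = np.argsort(net.plastic_pre, kind="stable")
    p_pre = net.plastic_pre[order_p]
    p_post = net.plastic_post[order_p]

    rows = []
    for item, ctxs in config.association_map.items():
        icells = np.zeros(net.n_neurons, dtype=bool)
        icells[net.pattern_cells(ITEM, item)] = True
        for ctx in ctxs:
            ccells = np.zeros(net.n_neurons, dtype=bool)
            ccells[net.pattern_cells(CONTEXT, ctx)] = True
            for direction, sel in (
                ("item->ctx", icells[p_pre] & ccells[p_post]),
                ("ctx->item", ccells[p_pre] & icells[p_post]),
            ):
                idx = np.flatnonzero(sel)
                for k in idx:
                    rows.append((item, ctx, len(ctxs), direction,
                                 float(wa[k]), float(wn[k])))
    return pd.DataFrame(
        rows, columns=["item", "ctx", "n_assoc", "direction", "w_fast", "w_slow"]
    )


def recall_table(trials: Sequence[TrialResult]) -> pd.DataFrame:
    """Mean recall per association count with Bernoulli SD across cues.

    For item cues, "recall" is context retrieval (remember-rate); for context
    cues it is retrieval of the associated item (an item event in the window:
    remember or know outcomes both require the target-side activation, so the
    associated-side score is outcome == 'remember').
    """
    frames = []
    for tr in trials:
        df = tr.outcomes.copy()
        df["trial_seed"] = tr.seed
        frames.append(df)
    allc = pd.concat(frames, ignore_index=True)
    allc["success"] = (allc["outcome"] == "remember").astype(float)
    rows = []
    for n_assoc, grp in allc.groupby("n_assoc"):
        p = grp["success"].mean()
        n = len(grp)
        rows.append((int(n_assoc), n, p, float(np.sqrt(p * (1 - p) / max(n, 1)))))
    return pd.DataFrame(rows, columns=["n_assoc", "n_cues", "recall", "sd"])


def per_context_recall(trials: Sequence[TrialResult], item: int,
                       config: ExperimentConfig) -> pd.DataFrame:
    """Fraction of trials each individual context is retrieved for one item cue."""
    ctxs = config.association_map[item]
    counts = {c: 0 for c in ctxs}
    n = 0
    for tr in trials:
        sel = tr.outcomes[(tr.outcomes.network == ITEM)
                          & (tr.outcomes.pattern == item)]
        if len(sel) == 0:
            continue
        n += 1
        recalled = sel.iloc[0]["recalled"]
        if recalled:
            for c in map(int, recalled.split(",")):
                counts[c] += 1
    return pd.DataFrame(
        {"context": list(counts), "recall": [counts[c] / max(n, 1) for c in counts]}
    )


def run_experiment(
    net: Network,
    config: ExperimentConfig,
    n_trials: Optional[int] = None,
    base_seed: int = 0,
    params: Optional[ModelParams] = None,
    keep_rasters: bool = False,
) -> Tuple[pd.DataFrame, List[TrialResult]]:
    """Run independently seeded trials and tabulate recall by association count.

    The structural network is shared across trials; trial-to-trial variation
    comes from the noise realization and the encoding order.  Returns the
    recall table and the trial list (rasters dropped unless requested).
    """
    n_trials = config.n_trials if n_trials is None else n_trials
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trials = [
        run_trial(net, config, seed=base_seed + 1000 * k, params=params,
                  keep_raster=keep_rasters)
        for k in range(n_trials)
    ]
    return recall_table(trials), trials
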