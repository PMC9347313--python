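"""Reduced seven-neuron microcircuit with continuous weight tracking.

Two item neurons form two and three context associations respectively
(item 0 with contexts {2, 3}; item 1 with contexts {4, 5, 6}); every
item-context pair is trained in its own 2 s epoch during which both neurons
are driven to fire at 20 Hz, and a final readout spike probes the weights
after training.  The plasticity kernels, neuron model, and all plasticity
parameters are exactly those of the full-scale network — the microcircuit
runs on the same simulation engine — so the continuous weight trajectories
expose the synaptic mechanism behind the large-scale results:

* under BCPNN, a synapse strengthens while its pair is co-stimulated and
  *weakens* when its item is re-encoded with a different context (the item's
  P_i keeps growing while the pair's P_ij decays), so the item with more
  context associations converges on weaker weights;
* under STDP, the synapse is simply untouched while its item fires with
  another context (pairings at second-scale lags are outside the plasticity
  window), so both items converge on similar weights regardless of their
  association count.

Firing is produced by suprathreshold periodic current pulses (deterministic
trajectories; the context neuron of each pair is driven with a small lag so
the presynaptic spike leads); a Poisson-drive alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Simulator
from .network import Network, PatternBook
from .params import ModelParams

DEFAULT_PAIRING_ORDER: Tuple[Tuple[int, int], ...] = (
    # (item neuron, context neuron) per 2 s epoch; interleaved so each item's
    # pairs are separated in time, matching the reference protocol
    (1, 4), (0, 2), (1, 5), (0, 3), (1, 6),
)


@dataclass
class MicroProtocol:
    """Roster, pairing schedule, and readout for the reduced model."""

    associations: Dict[int, Tuple[int, ...]] = field(
        default_factory=lambda: {0: (2, 3), 1: (4, 5, 6)}
    )
    pairing_order: Tuple[Tuple[int, int], ...] = DEFAULT_PAIRING_ORDER
    epoch_duration: float = 2000.0   # ms
    rate: float = 20.0               # target firing rate during an epoch, Hz
    readout_time: float = 11000.0    # ms, single presynaptic readout spike
    duration: float = 12000.0        # ms
    tracked: Tuple[Tuple[int, int], ...] = ((0, 2), (1, 4))
    stim: Literal["periodic", "poisson"] = "periodic"
    context_lag: float = 5.0         # ms, context pulses trail item pulses

    def __post_init__(self) -> None:
        n_ep = len(self.pairing_order)
        if self.readout_time < n_ep * self.epoch_duration:
            raise ValueError("readout must come after all training epochs")
        declared = {
            (i, c) for i, ctxs in self.associations.items() for c in ctxs
        }
        if not set(self.pairing_order) <= declared:
            raise ValueError("pairing order may only train declared pairs")
        if len(set(self.pairing_order)) != len(self.pairing_order):
            raise ValueError("each pair is trained in a single epoch")

    @property
    def n_neurons(self) -> int:
        return 1 + max(c for ctxs in self.associations.values() for c in ctxs)


def build_microcircuit(
    protocol: MicroProtocol, params: Optional[ModelParams] = None
) -> Network:
    """Wrap the seven neurons in a Network so the engine can run them.

    Item neurons are assigned to network 0 and context neurons to network 1;
    plastic synapses connect each item to its associated contexts in both
    directions at the minimal synaptic delay.  No recurrent or basket wiring.
    """
    params = params or ModelParams()
    n = protocol.n_neurons
    item_ids = sorted(protocol.associations)
    pre, post = [], []
    for item, ctxs in protocol.associations.items():
        for c in ctxs:
            pre += [item, c]
            post += [c, item]
    is_item = np.zeros(n, dtype=bool)
    is_item[item_ids] = True
    return Network(
        params=params,
        seed=0,
        is_pyr=np.ones(n, dtype=bool),
        network_id=np.where(is_item, 0, 1).astype(np.int32),
        hc=np.zeros(n, dtype=np.int32),
        mc=np.arange(n, dtype=np.int32),
        coords=np.zeros((n, 2)),
        static_pre=np.zeros(0, dtype=np.int64),
        static_post=np.zeros(0, dtype=np.int64),
        static_w_ampa=np.zeros(0),
        static_w_nmda=np.zeros(0),
        static_delay=np.zeros(0),
        static_stp=np.zeros(0, dtype=bool),
        plastic_pre=np.asarray(pre, dtype=np.int64),
        plastic_post=np.asarray(post, dtype=np.int64),
        plastic_delay=np.full(len(pre), params.connectivity.t_min_syn),
        patterns=PatternBook(n_patterns=1, layout=params.layout),
        unit_scale=1.0,
    )


def _pulse_events(neuron: int, t0: float, t1: float, rate: float,
                  amplitude: float = 9000.0, width: float = 2.0):
    """Suprathreshold current pulses producing one spike each at ``rate`` Hz."""
    period = 1000.0 / rate
    events = []
    t = t0
    while t < t1 - width:
        events.append((t, "i_ext", np.array([neuron]), amplitude))
        events.append((t + width, "i_ext", np.array([neuron]), 0.0))
        t += period
    return events


@dataclass
class MicroResult:
    protocol: MicroProtocol
    rule: str
    times: np.ndarray               # ms
    weights: pd.DataFrame           # time_s, synapse, w_fast, w_slow
    traces: pd.DataFrame            # BCPNN traces per tracked synapse
    spike_times: np.ndarray
    spike_neurons: np.ndarray

    def final_weight(self, pre: int, post: int, bank: str = "nmda") -> float:
        name = f"{pre}->{post}"
        col = "w_slow" if bank == "nmda" else "w_fast"
        sel = self.weights[self.weights.synapse == name]
        return float(sel[col].iloc[-1])

    def spike_count(self, neuron: int, t0: float, t1: float) -> int:
        m = (self.spike_neurons == neuron) & (self.spike_times >= t0) & (
            self.spike_times < t1
        )
        return int(m.sum())


def run_microcircuit(
    protocol: Optional[MicroProtocol] = None,
    rule: str = "bcpnn",
    seed: int = 0,
    params: Optional[ModelParams] = None,
    track_interval: float = 10.0,
) -> MicroResult:
    """Train the microcircuit and record tracked-synapse weight trajectories.

    All synapses of the roster are simulated; only the tracked ones are
    recorded.  With periodic stimulation the trajectories are deterministic
    (the seed only matters for the Poisson variant).
    """
    protocol = protocol or MicroProtocol()
    params = params or ModelParams()
    net = build_microcircuit(protocol, params)
    sim = Simulator(net, rule, params=params)

    events: List = []
    for k, (item, ctx) in enumerate(protocol.pairing_order):
        t0 = k * protocol.epoch_duration
        t1 = t0 + protocol.epoch_duration
        if protocol.stim == "periodic":
            events += _pulse_events(item, t0, t1, protocol.rate)
            events += _pulse_events(ctx, t0 + protocol.context_lag, t1,
                                    protocol.rate)
        else:
            cells_i = np.array([item])
            cells_c = np.array([ctx])
            # Poisson drive strong enough for ~20 Hz output
            events += [(t0, "stim_g", cells_i, 3.0),
                       (t0, "stim_rate", cells_i, 900.0),
                       (t1, "stim_rate", cells_i, 0.0),
                       (t0, "stim_g", cells_c, 3.0),
                       (t0, "stim_rate", cells_c, 900.0),
                       (t1, "stim_rate", cells_c, 0.0)]
    # final readout spike delivered to the presynaptic (item) neurons
    for item in sorted(protocol.associations):
        events += _pulse_events(item, protocol.readout_time,
                                protocol.readout_time + 3.0, protocol.rate)

    track_ids = [sim.synapse_index(a, b) for a, b in protocol.tracked]
    res = sim.run(
        protocol.duration, seed=seed, events=events,
        snapshot_times=[protocol.duration - 1.0],
        track_synapses=track_ids, track_interval=track_interval,
    )

    names = [f"{a}->{b}" for a, b in protocol.tracked]
    wrows, trows = [], []
    for r, t in enumerate(res.track_times):
        for j, name in enumerate(names):
            wrows.append((t / 1000.0, name,
                          res.track_w[r, j, 0], res.track_w[r, j, 1]))
            tr = res.track_traces[r, j]
            trows.append((t / 1000.0, name, *tr))
    weights = pd.DataFrame(wrows, columns=["time_s", "synapse", "w_fast", "w_slow"])
    traces = pd.DataFrame(
        trows,
        columns=["time_s", "synapse",
                 "Z_i_fast", "Z_j_fast", "P_i_fast", "P_j_fast", "P_ij_fast",
                 "Z_i_slow", "Z_j_slow", "P_i_slow", "P_j_slow", "P_ij_slow"],
    )
    return MicroResult(
        protocol=protocol, rule=rule, times=np.asarray(res.track_times),
        weights=weights, traces=traces,
        spike_times=res.spike_times, spike_neurons=res.spike_neurons,
    )


def trace_inspect(
    result: MicroResult, t_s: float, synapse: Tuple[int, int],
    bank: str = "nmda",
):
    """BCPNN trace snapshot (Z_i, Z_j, P_i, P_j, P_ij) at time ``t_s`` seconds."""
    from .bcpnn import BcpnnTraces

    if result.rule != "bcpnn":
        raise ValueError("trace inspection requires the BCPNN rule")
    name = f"{synapse[0]}->{synapse[1]}"
    sel = result.traces[result.traces.synapse == name]
    if len(sel) == 0:
        raise KeyError(f"synapse {name} was not tracked")
    tmin, tmax = sel.time_s.min(), sel.time_s.max()
    if not tmin <= t_s <= tmax:
        raise ValueError(f"t={t_s}s outside the recorded range [{tmin}, {tmax}]s")
    row = sel.iloc[(sel.time_s - t_s).abs().argmin()]
    sfx = "_slow" if bank == "nmda" else "_fast"
    return BcpnnTraces(
        Z_i=row[f"Z_i{sfx}"], Z_j=row[f"Z_j{sfx}"],
        P_i=row[f"P_i{sfx}"], P_j=row[f"P_j{sfx}"], P_ij=row[f"P_ij{sfx}"],
    )
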