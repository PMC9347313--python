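"""Multiplicative spike-timing-dependent plasticity (STDP).

Comparison rule for the associative internetwork pathway: weights are kept
normalized in [0, 1] and scaled by a per-receptor maximum conductance on
delivery, making the weight-dependent factors (1-w) and w well defined.

Pairing uses the delayed presynaptic arrival time: for a presynaptic spike
at t_i transmitted with delay tau_d and a postsynaptic spike at t_j,

    dt = t_j - (t_i + tau_d)

and the update is

    dw = +lambda * (1-w)^mu_plus  * exp(-|dt|/tau_plus)    if dt >= 0
    dw = -lambda * alpha * w^mu_minus * exp(-|dt|/tau_minus) otherwise

(the potentiation branch fires when the synaptic event precedes the
postsynaptic spike).  The scheme is nearest-neighbor: each event pairs with
the most recent opposite event.  Stability requires net depression over a
symmetric window, alpha*tau_minus/tau_plus > 1.

There is no bias-current plasticity in the STDP condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .params import StdpParams

_NEVER = -1.0e30  # sentinel "no event yet" time, ms


def stdp_delta(w_norm: float, delta_t: float, params: StdpParams) -> float:
    """Weight change for one pre/post pairing at lag ``delta_t`` (ms).

    ``delta_t`` is post time minus delayed pre arrival.  The result is
    clipped so the updated weight stays in [0, 1].
    """
    if not 0.0 <= w_norm <= 1.0:
        raise ValueError("w_norm must lie in [0, 1]")
    threshold = 0.0  # potentiation iff post follows the delayed pre arrival
    if params.branch_at_delay:
        # literal printed branch condition, kept for comparison
        threshold = getattr(params, "tau_d_branch", 0.0)
    if delta_t >= threshold:
        dw = params.lam * (1.0 - w_norm) ** params.mu_plus * np.exp(
            -abs(delta_t) / params.tau_plus
        )
    else:
        dw = -params.lam * params.alpha * w_norm ** params.mu_minus * np.exp(
            -abs(delta_t) / params.tau_minus
        )
    return float(np.clip(w_norm + dw, 0.0, 1.0) - w_norm)


@dataclass
class StdpState:
    """Per-synapse STDP state: normalized weight and last event times (ms)."""

    w_norm: float
    last_pre_arrival: float = _NEVER
    last_post: float = _NEVER


def stdp_on_spike(
    state: StdpState,
    event: Literal["pre-arrival", "post-spike"],
    t: float,
    params: StdpParams,
    tau_d: float = 0.0,
) -> StdpState:
    """Process one event with nearest-neighbor pairing.

    For ``event="pre-arrival"`` ``t`` is the presynaptic *emission* time; the
    arrival time ``t + tau_d`` is what enters the pairing.  Each event pairs
    with the most recent opposite event (if any).  Event times per synapse
    must be non-decreasing.
    """
    w = state.w_norm
    if event == "pre-arrival":
        if t + tau_d < state.last_pre_arrival - 1e-12:
            raise ValueError("presynaptic event times must be monotone")
        arrival = t + tau_d
        if state.last_post > _NEVER / 2:
            w += stdp_delta(w, state.last_post - arrival, params)
        return StdpState(w, last_pre_arrival=arrival, last_post=state.last_post)
    elif event == "post-spike":
        if t < state.last_post - 1e-12:
            raise ValueError("postsynaptic event times must be monotone")
        if state.last_pre_arrival > _NEVER / 2:
            w += stdp_delta(w, t - state.last_pre_arrival, params)
        return StdpState(w, last_pre_arrival=state.last_pre_arrival, last_post=t)
    raise ValueError(f"unknown event kind: {event!r}")


def run_pairings(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: StdpParams,
    tau_d: float = 0.0,
) -> np.ndarray:
    """Weight trajectory over merged pre/post spike trains (reference path).

    Returns the normalized weight after each processed event.  Presynaptic
    events are processed in *arrival* order so the nearest-neighbor pairing
    sees a single monotone event stream per synapse, matching the engine.
    """
    events = sorted(
        [(t + tau_d, "pre-arrival", t) for t in np.asarray(pre_spikes, float)]
        + [(t, "post-spike", t) for t in np.asarray(post_spikes, float)]
    )
    state = StdpState(w_norm=params.w0)
    out = []
    for _, kind, t in events:
        state = stdp_on_spike(state, kind, t, params, tau_d=tau_d)
        out.append(state.w_norm)
    return np.asarray(out)


def pairing_integral(params: StdpParams, w_norm: float = 0.5,
                     window: float = 100.0, n: int = 20001) -> float:
    """Numerical integral of dw over dt uniform in [-window, window].

    Negative for the reference parameters at the symmetric point w = 0.5:
    the condition for stable competitive modification.
    """
    dts = np.linspace(-window, window, n)
    return float(np.trapezoid([stdp_delta(w_norm, d, params) for d in dts], dts))


def states_to_frame(states) -> pd.DataFrame:
    """Columnar dump (connection id, w_norm, last event times) for checkpoints."""
    return pd.DataFrame(
        {
            "connection": np.arange(len(states)),
            "w_norm": [s.w_norm for s in states],
            "last_pre_arrival": [s.last_pre_arrival for s in states],
            "last_post": [s.last_post for s in states],
        }
    )
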