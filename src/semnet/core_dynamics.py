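"""Single-neuron and single-synapse dynamics (reference implementations).

These functions are the plain-NumPy statement of the model equations: the
adaptive exponential integrate-and-fire (AdEx) neuron with spike-triggered
adaptation, conductance-based synaptic currents, and Tsodyks-Markram
short-term plasticity.  The network engine (:mod:`semnet.engine`) re-states
the same update rules inside a compiled kernel; the functions here are used
directly for small simulations (PSP measurements, unit tests) and serve as
the independent reference the engine is checked against.

Integration is forward Euler.  A spike is registered when the membrane
potential crosses the numeric ceiling ``V_ceil`` (the exponential upstroke
diverges, so any ceiling well above threshold gives equivalent timing); on a
spike the potential is reset and clamped for the refractory period while the
adaptation current keeps decaying.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .params import NeuronParams, ReceptorParams, StpParams, RECEPTOR_NAMES

# cap on the exponential-upstroke argument; beyond this the neuron is spiking
# within the step anyway and exp() would overflow float64 around 709
_EXP_ARG_MAX = 16.0


@dataclass
class NeuronState:
    """Per-neuron state: membrane, adaptation, refractory clock, bias current."""

    V_m: float
    I_w: float = 0.0
    refractory_remaining: float = 0.0  # ms
    I_bias: float = 0.0                # pA, written by the BCPNN bias rule

    @classmethod
    def at_rest(cls, params: NeuronParams) -> "NeuronState":
        return cls(V_m=params.E_L)


def exp_upstroke(V_m, params: NeuronParams):
    """Exponential spike-initiation current g_L*Delta_T*exp((V-V_t)/Delta_T), pA."""
    arg = np.minimum((np.asarray(V_m) - params.V_t) / params.Delta_T, _EXP_ARG_MAX)
    return params.g_L * params.Delta_T * np.exp(arg)


def adex_step(
    state: NeuronState,
    params: NeuronParams,
    total_synaptic_current: float,
    I_ext: float,
    dt: float,
) -> Tuple[NeuronState, bool]:
    """One forward-Euler step of the AdEx membrane and adaptation equations.

    ``total_synaptic_current`` is signed with depolarizing currents positive
    (see :func:`synaptic_current`).  Returns the new state and a spike flag.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.V_m) and np.isfinite(state.I_w)):
        raise ValueError("non-finite neuron state")

    V, I_w, refr = state.V_m, state.I_w, state.refractory_remaining
    spiked = False

    # adaptation decays unconditionally
    I_w = I_w * (1.0 - dt / params.tau_Iw)

    if refr > 0.0:
        V = params.V_r
        refr = max(0.0, refr - dt)
    else:
        dV = (
            -params.g_L * (V - params.E_L)
            + float(exp_upstroke(V, params))
            - I_w
            + I_ext
            + total_synaptic_current
            + state.I_bias
        ) * (dt / params.C_m)
        V = V + dV
        if V >= params.V_ceil:
            spiked = True
            V = params.V_r
            I_w += params.b
            refr = params.tau_ref

    return NeuronState(V, I_w, refr, state.I_bias), spiked


def synaptic_current(
    V_m: float,
    conductances_by_receptor: Dict[str, float],
    receptors: Optional[ReceptorParams] = None,
) -> float:
    """Total synaptic current, pA, positive = depolarizing.

    Computes ``sum_syn g_syn * (E_syn - V_m)`` so that GABA is hyperpolarizing
    whenever V_m > E_GABA and AMPA/NMDA depolarizing whenever V_m < 0 mV.
    """
    receptors = receptors or ReceptorParams()
    total = 0.0
    for name, g in conductances_by_receptor.items():
        try:
            idx = RECEPTOR_NAMES.index(name)
        except ValueError:
            raise ValueError(f"unknown receptor label: {name!r}") from None
        if g < 0:
            raise ValueError("conductances must be non-negative")
        total += g * (receptors.reversal(idx) - V_m)
    return total


@dataclass
class StpState:
    """Tsodyks-Markram state: utilization u (augmentation) and resources x."""

    u: float = 0.0
    x: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.x <= 1.0):
            raise ValueError("u and x must lie in [0, 1]")


def stp_update(
    state: StpState, params: StpParams, spike: bool, dt: float
) -> Tuple[StpState, float]:
    """One step of the short-term plasticity dynamics.

    Between spikes u decays toward 0 with tau_A and x recovers toward 1 with
    tau_D.  On a presynaptic spike, u jumps by U*(1-u) and x drops by U*x.
    Returns the new state and the release factor for a spike in this step
    (``u_post * x_pre``: post-jump utilization acting on pre-jump resources),
    or 0.0 if no spike occurred.  With augmentation disabled, u is pinned to
    U on every spike instead of accumulating.
    """
    u = state.u * np.exp(-dt / params.tau_A)
    x = 1.0 - (1.0 - state.x) * np.exp(-dt / params.tau_D)
    release = 0.0
    if spike:
        x_pre = x
        if params.enabled:
            u = u + params.U * (1.0 - u)
        else:
            u = params.U
        x = x - params.U * x
        release = u * x_pre
    return StpState(u, x), release


def stp_release_train(
    spike_times: np.ndarray, params: StpParams
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-by-event STP along a spike train (times in ms, strictly increasing).

    Returns arrays (u_post, x_pre, release) per spike; this is the exact
    event-driven solution used by the network engine.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    u, x = 0.0, 1.0
    t_last = None
    u_out, x_out, r_out = [], [], []
    for t in spike_times:
        if t_last is not None:
            if t <= t_last:
                raise ValueError("spike times must be strictly increasing")
            dt = t - t_last
            u = u * np.exp(-dt / params.tau_A)
            x = 1.0 - (1.0 - x) * np.exp(-dt / params.tau_D)
        x_pre = x
        u = u + params.U * (1.0 - u) if params.enabled else params.U
        x = x - params.U * x
        u_out.append(u)
        x_out.append(x_pre)
        r_out.append(u * x_pre)
        t_last = t
    return np.array(u_out), np.array(x_out), np.array(r_out)


def poisson_background(
    rate: float,
    g_unit: float,
    duration: float,
    dt: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Zero-mean background drive: two independent Poisson event streams.

    One stream drives a ``+g_unit`` conductance at the excitatory reversal,
    the other a ``g_unit`` conductance at the inhibitory (GABA) reversal, so
    the injected current is zero-mean at the symmetric point of the two
    driving forces.  Returns two arrays of per-step event counts over
    ``duration`` ms.  ``rate`` is per generator, Hz.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = int(round(duration / dt))
    lam = rate * dt * 1e-3
    exc = rng.poisson(lam, size=n)
    inh = rng.poisson(lam, size=n)
    return exc, inh


def resting_potential(params: NeuronParams) -> float:
    """Fixed point of the subthreshold dynamics with no input (root finding)."""
    from scipy.optimize import brentq

    def f(V):
        return -params.g_L * (V - params.E_L) + float(exp_upstroke(V, params))

    # bracket between a deeply hyperpolarized point and just below threshold
    return float(brentq(f, params.E_L - 20.0, params.V_t - 1.0))


def holding_current(V_hold: float, params: NeuronParams) -> float:
    """Constant current that makes V_hold a subthreshold equilibrium, pA."""
    return params.g_L * (V_hold - params.E_L) - float(exp_upstroke(V_hold, params))


def simulate_voltage(
    params: NeuronParams,
    receptors: ReceptorParams,
    duration: float,
    dt: float,
    conductance_events: Dict[int, list],
    I_ext: float = 0.0,
    V0: Optional[float] = None,
    I_bias: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a single neuron under scheduled conductance events.

    ``conductance_events`` maps receptor index -> list of (time ms, nS)
    increments to that receptor's exponentially decaying conductance.
    Returns (t, V, spikes) with spike times in ms.  Used by the PSP
    measurement harness and the single-neuron tests.
    """
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    V = np.empty(n)
    g = np.zeros(4)
    decay = np.exp(-dt / np.asarray(receptors.tau_syn))
    events = {
        r: sorted(ev) for r, ev in conductance_events.items() if len(ev) > 0
    }
    ptr = {r: 0 for r in events}
    state = NeuronState(V_m=params.E_L if V0 is None else V0, I_bias=I_bias)
    spikes = []
    for k in range(n):
        now = t[k]
        for r, ev in events.items():
            i = ptr[r]
            while i < len(ev) and ev[i][0] <= now:
                g[r] += ev[i][1]
                i += 1
            ptr[r] = i
        I_syn = float(np.sum(g * (np.asarray(receptors.E_rev) - state.V_m)))
        state, spiked = adex_step(state, params, I_syn, I_ext, dt)
        if spiked:
            spikes.append(now)
        V[k] = state.V_m
        g *= decay
    return t, V, np.array(spikes)
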