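"""Spike-based Bayesian-Hebbian (BCPNN) plasticity.

The rule keeps, per connection, exponentially averaged traces of pre-, post-
and co-activation on two time scales: fast Z traces (one bank with the AMPA
time constant, one with the NMDA time constant) and slow P traces shared
between the banks through a common ``tau_p``.  Weights are the log odds of
coactivation against independence, and each cell carries a log-prior bias
current:

    w_ij   = w_gain * log( P_ij / (P_i * P_j) )
    beta_j = beta_gain * log( P_j )

Z dynamics:   tau_z dZ/dt = (spike drive) - Z + eps
P dynamics:   tau_p dP/dt = kappa * (Z - P)        (P_ij driven by Z_i*Z_j)

Spikes enter the Z drive as pulses calibrated so that sustained firing at
``f_max`` yields a time-averaged Z of ~1 (here: an instantaneous increment
of 1/(f_max*tau_z) per spike, the integral-equivalent of a 1 ms rectangular
pulse of height 1/(f_max*t_spike)).  With no spikes Z decays to the floor
``eps``; traces therefore never fall below eps (floor constant c = 1), and
P_ij is initialized to eps^2 = P_i*P_j so initial weights are exactly zero.

``kappa`` scales the learning rate of the P stage only; kappa = 0 freezes
weights and biases bit-exactly.

All functions are vectorized over arrays of traces and are the exact
per-step discretization (exponential decay between events, jumps at spikes)
that the compiled network engine uses, so trace trajectories agree to
floating-point accuracy on identical spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .params import BcpnnParams

ArrayLike = Union[float, np.ndarray]


@dataclass
class BcpnnTraces:
    """Trace state for one bank of one (or an array of) connection(s)."""

    Z_i: ArrayLike
    Z_j: ArrayLike
    P_i: ArrayLike
    P_j: ArrayLike
    P_ij: ArrayLike

    @classmethod
    def initial(cls, params: BcpnnParams, shape=()) -> "BcpnnTraces":
        """Naive-prior start: P_i = P_j = eps, P_ij = eps^2 (zero weight)."""
        e = params.epsilon
        full = lambda v: np.full(shape, v) if shape else v
        return cls(full(e), full(e), full(e), full(e), full(e * e))

    def copy(self) -> "BcpnnTraces":
        c = lambda a: np.array(a, copy=True) if isinstance(a, np.ndarray) else a
        return BcpnnTraces(*(c(getattr(self, f)) for f in
                             ("Z_i", "Z_j", "P_i", "P_j", "P_ij")))


def z_update(
    Z: ArrayLike, spikes: ArrayLike, tau_z: float, params: BcpnnParams, dt: float
) -> ArrayLike:
    """One step of the Z trace: exact exponential decay toward eps plus spike jumps.

    ``spikes`` is a 0/1 flag (or array of flags) for this step.  kappa plays
    no role at this stage.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = np.exp(-dt / tau_z)
    Z = params.epsilon + (Z - params.epsilon) * d
    return Z + np.asarray(spikes) * params.z_jump(tau_z)


def p_update(
    traces: BcpnnTraces, params: BcpnnParams, dt: float, kappa: ArrayLike = None
) -> BcpnnTraces:
    """One step of the P trace relaxation toward the Z traces.

    Uses the exact exponential-Euler factor ``1 - exp(-kappa*dt/tau_p)`` so
    that kappa = 0 leaves the traces bit-identical and large steps remain
    stable.  ``kappa`` may be a scalar or per-connection array; defaults to
    the parameter value.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = params.kappa if kappa is None else kappa
    fac = -np.expm1(-np.asarray(k) * dt / params.tau_p)
    return BcpnnTraces(
        Z_i=traces.Z_i,
        Z_j=traces.Z_j,
        P_i=traces.P_i + (traces.Z_i - traces.P_i) * fac,
        P_j=traces.P_j + (traces.Z_j - traces.P_j) * fac,
        P_ij=traces.P_ij + (traces.Z_i * traces.Z_j - traces.P_ij) * fac,
    )


def weight_and_bias(
    traces: BcpnnTraces, params: BcpnnParams, bank: str = "nmda"
) -> Tuple[ArrayLike, ArrayLike]:
    """Log-odds weight (nS) and log-prior bias (pA) from the P traces.

    Weights may be negative (coactivation below independence).  Raises on
    non-positive P traces, which are outside the reachable state space.
    """
    for name in ("P_i", "P_j", "P_ij"):
        if np.any(np.asarray(getattr(traces, name)) <= 0):
            raise ValueError(f"{name} must be positive for the log-odds weight")
    w_gain = params.w_gain_nmda if bank == "nmda" else params.w_gain_ampa
    w = w_gain * np.log(traces.P_ij / (traces.P_i * traces.P_j))
    beta = params.beta_gain * np.log(traces.P_j)
    return w, beta


def run_traces(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: BcpnnParams,
    tau_z: float,
    duration: float,
    dt: float,
    kappa: float = None,
    kappa_schedule=None,
    record_every: int = 1,
    p_every: int = 1,
) -> pd.DataFrame:
    """Integrate one connection's trace cascade over explicit spike trains.

    ``pre_spikes``/``post_spikes`` are spike times in ms.  ``kappa_schedule``
    is an optional callable t_ms -> kappa overriding the constant value.
    ``p_every`` relaxes the P stage only every that many steps (with the
    correspondingly larger exact exponential factor), matching the network
    engine's coarse P-update grid when set to its value.
    Returns a tidy DataFrame with columns t, Z_i, Z_j, P_i, P_j, P_ij.
    Reference path for tests and for the microcircuit trace inspection.
    """
    n = int(round(duration / dt))
    pre = np.zeros(n, dtype=bool)
    post = np.zeros(n, dtype=bool)
    pre[np.minimum(np.round(np.asarray(pre_spikes) / dt).astype(int), n - 1)] = True
    post[np.minimum(np.round(np.asarray(post_spikes) / dt).astype(int), n - 1)] = True
    if len(pre_spikes) == 0:
        pre[:] = False
    if len(post_spikes) == 0:
        post[:] = False

    tr = BcpnnTraces.initial(params)
    k_const = params.kappa if kappa is None else kappa
    rows = []
    for i in range(n):
        t = i * dt
        tr.Z_i = z_update(tr.Z_i, pre[i], tau_z, params, dt)
        tr.Z_j = z_update(tr.Z_j, post[i], tau_z, params, dt)
        if i % p_every == p_every - 1:
            k = k_const if kappa_schedule is None else kappa_schedule(t)
            tr = p_update(tr, params, dt * p_every, kappa=k)
        if i % record_every == 0:
            rows.append((t, tr.Z_i, tr.Z_j, tr.P_i, tr.P_j, tr.P_ij))
    return pd.DataFrame(rows, columns=["t", "Z_i", "Z_j", "P_i", "P_j", "P_ij"])


@dataclass
class TraceBank:
    """Vectorized trace state for a set of plastic connections (one bank).

    Thin container used for checkpointing and tests; the network engine keeps
    the same arrays in flat form.
    """

    params: BcpnnParams
    tau_z: float
    traces: BcpnnTraces
    kappa: np.ndarray = field(default=None)

    @classmethod
    def create(cls, n: int, params: BcpnnParams, tau_z: float) -> "TraceBank":
        return cls(
            params=params,
            tau_z=tau_z,
            traces=BcpnnTraces.initial(params, shape=(n,)),
            kappa=np.full(n, params.kappa),
        )

    def set_kappa(self, idx, kappa: float) -> None:
        """Set the learning-rate gain for a subset of connections."""
        if kappa < 0:
            raise ValueError("kappa must be non-negative")
        self.kappa[idx] = kappa

    def to_frame(self) -> pd.DataFrame:
        """Columnar dump (connection id, Z_i, Z_j, P_i, P_j, P_ij) for checkpoints."""
        t = self.traces
        return pd.DataFrame(
            {
                "connection": np.arange(len(np.asarray(t.P_ij))),
                "Z_i": t.Z_i, "Z_j": t.Z_j,
                "P_i": t.P_i, "P_j": t.P_j, "P_ij": t.P_ij,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, params: BcpnnParams, tau_z: float
    ) -> "TraceBank":
        tr = BcpnnTraces(
            Z_i=df["Z_i"].to_numpy().copy(), Z_j=df["Z_j"].to_numpy().copy(),
            P_i=df["P_i"].to_numpy().copy(), P_j=df["P_j"].to_numpy().copy(),
            P_ij=df["P_ij"].to_numpy().copy(),
        )
        return cls(params=params, tau_z=tau_z, traces=tr,
                   kappa=np.full(len(df), params.kappa))
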