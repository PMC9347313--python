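"""Model parameters.

Every dataclass below mirrors one block of the published parameter tables
(neuron/synapse, BCPNN, STDP, layout/connectivity/stimulation).  Defaults are
the reference values of the model; everything is overridable via keyword
arguments or a YAML config file (see :func:`load_config`).

Units follow the conventions of the field: membrane quantities in pF/nS/mV/pA,
times in ms unless a field name says seconds, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from typing import Dict, Tuple

import yaml

# receptor buffer indices used throughout the engine:
#   0: fast excitatory  (AMPA,  tau 5 ms,   E = 0 mV)
#   1: slow excitatory  (NMDA,  tau 100 ms, E = 0 mV)
#   2: fast inhibitory  (GABA,  tau 5 ms,   E = -75 mV)
#   3: slow inhibitory  (negative slow-bank weights, tau 100 ms, E = -75 mV)
AMPA, NMDA, GABA, GABA_SLOW = 0, 1, 2, 3
RECEPTOR_NAMES = ("AMPA", "NMDA", "GABA", "GABA_SLOW")


@dataclass
class NeuronParams:
    """AdEx neuron with spike-triggered adaptation (no subthreshold adaptation)."""

    C_m: float = 280.0        # membrane capacitance, pF
    g_L: float = 14.0         # leak conductance, nS
    E_L: float = -70.6        # leak reversal, mV
    Delta_T: float = 3.0      # upstroke slope factor, mV
    V_t: float = -55.0        # spike threshold, mV
    V_r: float = -60.0        # reset potential, mV
    b: float = 86.0           # spike-triggered adaptation increment, pA
    tau_Iw: float = 280.0     # adaptation decay time constant, ms
    tau_ref: float = 5.0      # absolute refractory period, ms
    # numeric spike-detection ceiling; the exponential term diverges above
    # threshold so any ceiling well above V_t gives sub-dt equivalent timing
    V_ceil: float = 0.0       # mV

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if min(self.tau_Iw, self.tau_ref, self.Delta_T) <= 0:
            raise ValueError("time constants and Delta_T must be positive")
        if self.V_r > self.V_t:
            raise ValueError("reset potential must not exceed threshold")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m/g_L, ms."""
        return self.C_m / self.g_L


@dataclass
class ReceptorParams:
    """Conductance kinetics per receptor buffer (exponential decay kernels)."""

    tau_syn: Tuple[float, float, float, float] = (5.0, 100.0, 5.0, 100.0)  # ms
    E_rev: Tuple[float, float, float, float] = (0.0, 0.0, -75.0, -75.0)    # mV

    def tau(self, receptor: int) -> float:
        return self.tau_syn[receptor]

    def reversal(self, receptor: int) -> float:
        return self.E_rev[receptor]


@dataclass
class StpParams:
    """Tsodyks-Markram short-term augmentation (u) and depression (x)."""

    U: float = 0.2            # utilization fraction per spike
    tau_A: float = 5000.0     # augmentation decay, ms (5 s)
    tau_D: float = 280.0      # depression recovery, ms
    enabled: bool = True      # False pins u to U on each spike (no augmentation)

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= 1.0:
            raise ValueError("U must lie in [0, 1]")
        if self.tau_A <= 0 or self.tau_D <= 0:
            raise ValueError("STP time constants must be positive")


@dataclass
class BcpnnParams:
    """Spike-based Bayesian-Hebbian (BCPNN) plasticity parameters.

    Two trace banks run per plastic connection: a fast bank with the AMPA
    time constant and a slow bank with the NMDA time constant, each with its
    own conductance gain; both share ``tau_p``.  ``f_min`` is carried for
    completeness (it appears in the reference parameter table) but enters no
    equation here.
    """

    f_max: float = 25.0       # maximal spiking rate used for trace calibration, Hz
    f_min: float = 0.2        # lowest spiking rate, Hz (parameterized, unused)
    epsilon: float = 0.0026   # lowest attainable probability estimate
    tau_z_ampa: float = 5.0   # fast-bank Z time constant, ms
    tau_z_nmda: float = 100.0  # slow-bank Z time constant, ms
    tau_p: float = 15000.0    # P trace time constant, ms (15 s)
    kappa: float = 1.0        # baseline learning-rate gain (kappa_normal)
    kappa_boost: float = 2.0  # modulated learning-rate gain
    w_gain_ampa: float = 0.76  # fast-bank weight gain, nS
    w_gain_nmda: float = 0.07  # slow-bank weight gain, nS
    beta_gain: float = 40.0   # intrinsic-excitability (bias) gain, pA
    t_spike: float = 1.0      # nominal spike pulse duration, ms (calibration only)
    # Initial (and floor) value of the per-cell bias probability trace for
    # cells hosting consolidated attractors: the activation probability
    # learned during preloading.  Calibrated functionally, together with the
    # preloaded weights, so that a 50 ms cue completes a stored attractor
    # against background noise while the baseline stays quiescent.
    bias_prior: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not (self.tau_z_ampa < self.tau_p and self.tau_z_nmda < self.tau_p):
            raise ValueError("tau_z must be smaller than tau_p")

    def z_jump(self, tau_z: float) -> float:
        """Per-spike Z increment.

        A spike contributes a pulse of area ``t_spike`` * height
        ``1/(f_max*t_spike)`` to the Z drive; delivered as an instantaneous
        increment ``1/(f_max*tau_z)`` it has the same integral, so sustained
        firing at f_max gives a time-averaged Z of eps + 1 ~= 1.
        """
        return 1.0 / (self.f_max * tau_z * 1e-3)


@dataclass
class StdpParams:
    """Multiplicative (weight-dependent) STDP for the associative pathway."""

    w0: float = 0.0           # initial normalized weight
    w_max_ampa: float = 13.5  # fast-component conductance scale, nS
    w_max_nmda: float = 3.5   # slow-component conductance scale, nS
    lam: float = 0.01         # learning rate
    alpha: float = 1.2        # depression/potentiation asymmetry
    mu_plus: float = 1.0      # weight-dependence exponent, potentiation
    mu_minus: float = 1.0     # weight-dependence exponent, depression
    tau_plus: float = 20.0    # potentiation window, ms
    tau_minus: float = 20.0   # depression window, ms
    # Pairing scheme: nearest neighbor (each event pairs with the most recent
    # opposite event).  `branch_at_delay=True` switches to the literal printed
    # branch condition (potentiation iff dt >= transmission delay).
    branch_at_delay: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.w0 <= 1.0:
            raise ValueError("w0 must lie in [0, 1]")
        if self.alpha * self.tau_minus / self.tau_plus <= 1.0:
            raise ValueError(
                "stability requires alpha*tau_minus/tau_plus > 1 "
                "(net depression over a symmetric window)"
            )
        if self.mu_plus not in (0.0, 1.0) or self.mu_minus not in (0.0, 1.0):
            raise ValueError("mu exponents must be 0 (additive) or 1 (multiplicative)")


@dataclass
class LayoutParams:
    """Modular two-network geometry: hypercolumns (HC) of minicolumns (MC)."""

    n_hc: int = 12            # hypercolumns per network
    n_mc_per_hc: int = 10     # minicolumns per hypercolumn
    n_pyr_per_mc: int = 30    # layer 2/3 pyramidal cells per minicolumn
    n_basket_per_mc: int = 2  # basket cells per minicolumn
    hc_diameter: float = 0.5  # mm
    patch_size: Tuple[float, float] = (2.0, 1.5)   # cortical patch, mm
    internetwork_distance: float = 10.0            # mm between the two networks
    n_items: int = 4          # stored item patterns actually used in the task
    n_contexts: int = 10      # stored context patterns used in the task

    def __post_init__(self) -> None:
        if self.n_items > self.n_mc_per_hc or self.n_contexts > self.n_mc_per_hc:
            raise ValueError(
                "pattern count cannot exceed minicolumns per hypercolumn "
                "(patterns are non-overlapping: one selective MC per HC)"
            )

    @property
    def n_pyr_per_network(self) -> int:
        return self.n_hc * self.n_mc_per_hc * self.n_pyr_per_mc

    @property
    def n_basket_per_network(self) -> int:
        return self.n_hc * self.n_mc_per_hc * self.n_basket_per_mc

    @property
    def n_pyr_total(self) -> int:
        return 2 * self.n_pyr_per_network

    @property
    def n_basket_total(self) -> int:
        return 2 * self.n_basket_per_network


@dataclass
class ConnectivityParams:
    """Connection probabilities, conductances, and delay model."""

    cp_pp: float = 0.2        # within-HC pyramidal-pyramidal (recurrent)
    cp_ppl: float = 0.25      # cross-HC pyramidal-pyramidal (long-range)
    cp_ppa: float = 0.02      # associative internetwork pyramidal-pyramidal
    cp_pb: float = 0.7        # pyramidal -> basket, within HC
    cp_bp: float = 0.7        # basket -> pyramidal, within HC
    g_pb: float = 3.0         # pyramidal -> basket conductance, nS
    g_bp: float = -7.0        # basket -> pyramidal conductance, nS
    speed: float = 0.2        # axonal conduction speed within a network, m/s
    speed_myelinated: float = 2.0  # internetwork (myelinated) speed, m/s
    t_min_syn: float = 1.5    # minimal synaptic delay, ms
    delay_jitter_rel: float = 0.3  # relative SD of the delay distribution

    # --- attractor preloading (see network module docstring) ---
    # Mean of the positive preloaded weight distribution in model (log-odds)
    # units, and the within-HC : cross-HC mean ratio; the single nS scaling
    # factor is calibrated against the within-HC EPSP observable (0.45 mV).
    attractor_mean: float = 2.1        # model units, overall positive mean
    attractor_local_ratio: float = 1.2  # within-HC mean / cross-HC mean
    competing_mean: float = -0.3       # model units, competing-MC mean
    attractor_cv: float = 0.29         # relative SD of preloaded weights
    unit_scale: float = 1.0            # model-unit -> nS factor (calibrated)
    # Fan-in-preserving downscale compensation.  Networks smaller than the
    # reference layout have proportionally fewer recurrent and associative
    # synapses per cell; these gains multiply the *delivered* conductance so
    # the total recurrent/associative current per cell is preserved.  Both
    # are 1.0 at the reference (12-HC) scale.  Reported weight distributions
    # are always the unscaled learned weights.
    recurrent_gain: float = 1.0
    associative_gain: float = 1.0


@dataclass
class StimulationParams:
    """Background noise and pattern-specific drive (reference stimulation table)."""

    bg_rate_pyr_encoding: float = 650.0  # Hz (see bg_per_generator)
    bg_rate_pyr_recall: float = 450.0    # Hz
    bg_rate_basket: float = 75.0         # Hz
    # Whether the table rates apply to each generator of the +/- pair or to
    # the pair summed (each generator at rate/2, the default).  The summed
    # reading keeps the trained network in the cued-recall regime; the
    # per-generator reading doubles the noise fluctuations and pushes it
    # into spontaneous (free) recall.
    bg_per_generator: bool = False
    g_bg: float = 1.5                    # +/- background conductance, nS
    t_stim: float = 250.0                # encoding stimulus duration, ms
    r_stim: float = 500.0                # encoding stimulation rate, Hz
    t_cue: float = 50.0                  # cue duration, ms
    r_cue: float = 400.0                 # cue stimulation rate, Hz
    g_stim: float = 1.5                  # stimulation/cue conductance, nS
    isi: float = 500.0                   # interstimulus interval, ms
    t_settle: float = 250.0              # noise-only settling before encoding, ms
    t_delay: float = 1000.0              # encoding -> test delay, ms
    cue_window: float = 500.0            # scoring window per cue, ms


@dataclass
class DetectorParams:
    """Attractor-activation detector (population-rate EMA + hysteresis)."""

    tau: float = 40.0         # EMA filter time constant, ms
    dT: float = 1.0           # sampling interval, ms
    n_pop: int = 30           # pattern-selective population size (one MC)
    r_th: float = 10.0        # detection threshold, Hz
    min_duration: float = 40.0      # minimal supra-threshold duration, ms
    recross_guard: float = 40.0     # offset guard against brief dips, ms
    sample_hc: int = 0        # HC whose selective MC populations are monitored
    literal_recursion: bool = False  # printed (non-EMA) recursion, for comparison

    def __post_init__(self) -> None:
        if self.dT >= self.tau:
            raise ValueError("sampling interval must be below the filter time constant")
        if self.r_th <= 0:
            raise ValueError("detection threshold must be positive")


@dataclass
class SimParams:
    """Numerical integration settings."""

    dt: float = 0.1           # integration step, ms (forward Euler)
    p_update_interval: float = 1.0  # P-trace / bias update interval, ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ModelParams:
    """Bundle of every parameter block of the model."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    stp: StpParams = field(default_factory=StpParams)
    bcpnn: BcpnnParams = field(default_factory=BcpnnParams)
    stdp: StdpParams = field(default_factory=StdpParams)
    layout: LayoutParams = field(default_factory=LayoutParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    stimulation: StimulationParams = field(default_factory=StimulationParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    sim: SimParams = field(default_factory=SimParams)

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelParams":
        kwargs = {}
        for f in fields(cls):
            block = d.get(f.name, {})
            block = dict(block)
            # tuples round-trip through YAML as lists
            for k, v in block.items():
                if isinstance(v, list):
                    block[k] = tuple(v)
            kwargs[f.name] = f.default_factory().__class__(**block)  # type: ignore[misc]
        return cls(**kwargs)

    def with_layout(self, **kw) -> "ModelParams":
        return replace(self, layout=replace(self.layout, **kw))


def _same_pattern_recurrent_fan_in(layout: LayoutParams, conn: ConnectivityParams) -> float:
    p = layout.n_pyr_per_mc
    return (p - 1) * conn.cp_pp + (layout.n_hc - 1) * p * conn.cp_ppl


def _associative_fan_in(layout: LayoutParams, conn: ConnectivityParams) -> float:
    return layout.n_hc * layout.n_pyr_per_mc * conn.cp_ppa


def reduced_params(n_hc: int = 6) -> ModelParams:
    """Desk-scale parameter set: fewer hypercolumns, all else unchanged.

    Delivered recurrent conductances are scaled up by the ratio of
    reference-scale to reduced-scale expected same-pattern fan-in, preserving
    the total recurrent current per cell: without this the preloaded
    attractors of a downsampled network cannot complete from a cue.  The
    plastic associative pathway keeps its native strength (every parameter as
    at full scale), so the reduced network carries proportionally less
    associative drive per cell — recall rates shift down but keep their shape
    over association counts.
    """
    params = ModelParams()
    ref_lay, conn = params.layout, params.connectivity
    lay = replace(ref_lay, n_hc=n_hc)
    rec_gain = _same_pattern_recurrent_fan_in(ref_lay, conn) / _same_pattern_recurrent_fan_in(lay, conn)
    return replace(
        params,
        layout=lay,
        connectivity=replace(conn, recurrent_gain=rec_gain),
    )


def load_config(path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh) or {})


def save_config(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
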