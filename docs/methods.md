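# Model and methods

`semnet` simulates a cortical "network of networks" account of how episodic
memories lose their contextual detail (semantization): an Item network and a
Context network, each a modular attractor memory, are linked by a sparse
plastic associative pathway.  Items encoded in many different contexts end up
with weaker item-context bindings than items encoded once — under
Bayesian-Hebbian (BCPNN) learning, but not under spike-timing-dependent
plasticity (STDP) — because Bayesian weights are normalized by the estimated
marginal activation probabilities of the connected cells.

## Neurons and synapses

Cells are adaptive exponential integrate-and-fire (AdEx) point neurons with
spike-triggered adaptation only (no subthreshold adaptation term):

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_t)/Δ_T)
                - I_w + I_ext + I_bias + I_syn
    dI_w/dt   = -I_w/τ_Iw + b δ(t - t_spike)

with C_m = 280 pF, g_L = 14 nS, E_L = −70.6 mV, Δ_T = 3 mV, V_t = −55 mV,
reset V_r = −60 mV, b = 86 pA, τ_Iw = 280 ms, refractory 5 ms.  Integration
is forward Euler at dt = 0.1 ms; a spike is registered when V crosses 0 mV
(the exponential upstroke diverges, so any ceiling well above V_t gives
equivalent timing; halving dt moves spike times by well under 0.5 ms, which
the suite verifies).  Measurements that need higher accuracy (PSP amplitudes)
use the same equations at dt = 0.01 ms.

Synapses are conductance-based with exponential kernels on four buffers per
neuron: fast and slow excitatory (τ = 5 / 100 ms, E = 0 mV) and fast and
slow inhibitory (τ = 5 / 100 ms, E = −75 mV).  The slow excitatory
(NMDA-like) component carries no voltage-dependent block; it differs from
the fast (AMPA-like) component only by its time constant and gain.  Negative
weights — the preloaded competition between attractors and any negative
learned log-odds weight — are delivered at the inhibitory reversal with
their component's own time constant: a monosynaptic stand-in for the
disynaptic inhibition that double-bouquet cells would provide (those cells
are not simulated explicitly).

Every pyramidal-sourced synapse is subject to Tsodyks-Markram short-term
plasticity with slow augmentation: utilization u decays toward 0 with
τ_A = 5 s, resources x recover toward 1 with τ_D = 280 ms, a spike jumps
u by U(1−u) and consumes U·x of the resources (U = 0.2), and the delivered
conductance is w·u⁺·x⁻ (post-jump utilization acting on pre-jump resources;
this makes the first spike from rest transmit exactly U·w).  The basket-cell
feedback loop (pyramidal→basket and basket→pyramidal) is static: depressing
the winner-take-all circuit makes local competition unreliable.
Augmentation can be disabled (u pinned to U per spike), with optional
compensation hooks that raise the stimulation rates and gain.

## Architecture

Each network is a grid of 12 hypercolumns (HC, 0.5 mm across, tiled over a
2.0 × 1.5 mm patch), each with 10 minicolumns (MC) of 30 pyramidal cells
plus 2 basket cells — 7200 excitatory and 480 inhibitory cells in total.
Stored patterns are non-overlapping: pattern p is MC p of every HC.
Connectivity is Bernoulli: within-HC same-pattern pyramidal pairs at 0.2,
cross-HC same-pattern pairs at 0.25, competing (different-MC) pairs at the
same probabilities with negative weights, pyramidal↔basket within HC at 0.7
(+3 / −7 nS), and plastic associative projections between the networks at
0.02 in both directions.  Conduction delays are drawn from
N(d/V + 1.5 ms, 0.3·mean), truncated below at 1.5 ms, with V = 0.2 m/s
within a network and 2 m/s (myelinated) for the 10 mm between networks.

### Attractor preloading and calibration

The recurrent weights encode consolidated long-term memories and stay fixed
through the task.  They are drawn in model (log-odds) units — positive
same-pattern weights with an overall mean of 2.1 (within-HC mean 1.2× the
cross-HC mean; relative SD 29%), competing weights with mean −0.3 — and
converted to conductances through the two BCPNN gains (0.76 nS fast,
0.07 nS slow) times a single scale factor.  That factor is the model's one
preload calibration: it is set so the mean within-HC same-pattern EPSP,
measured at rest with the first-spike release factor (u = U, x = 1), equals
0.45 mV.  The resulting unitary basket→pyramidal IPSP at −60 mV is
−1.18 mV, a direct consequence of the fixed −7 nS conductance and the AdEx
membrane.  The measurement harness reports both the first-spike-scaled and
bare-conductance PSP conventions.

The first-spike convention for the calibration is a deliberate choice:
during sustained firing the release factor u·x settles near U, so the
effective recurrent EPSP inside a burst stays close to the calibrated
0.45 mV and cue-driven pattern completion is regenerative ("explosive").
Calibrating on the bare conductance instead makes stored attractors five
times weaker and they then fail to complete from a 50 ms cue — verified
numerically, which is why that convention is rejected.

### Intrinsic excitability (bias)

Every pyramidal cell carries a bias current β = β_gain · ln(P_j)
(β_gain = 40 pA) driven by its own slow activation trace.  Two departures
from a literal reading of the trace equations were necessary and are the
package's own modeling choices:

* The bias trace estimates an activation *probability*, so its drive
  saturates at 1 (firing above f_max cannot make a cell more than certainly
  active) and β never becomes positive.  Without the cap, encoding bursts
  (30–120 Hz ≫ f_max = 25 Hz) push P_j far above 1 and the accumulated
  positive bias tips the network into spontaneous (free) recall.
* The bias trace is initialized at, and floored by, a consolidated
  activation prior p₀ = 0.35.  The preloaded attractors come from prior
  learning, which would have set the biases along with the weights; a naive
  ε start (β ≈ −239 pA on every cell) silences the network outright, and one
  task should not erode excitability learned over long prior experience.
  p₀ is the model's operating-point calibration: it is set (together with
  the preload scale) so that a 50 ms / 400 Hz cue reliably completes a
  stored attractor against recall background noise while the baseline stays
  quiescent.  It is deliberately not derived from the 1/n_MC pattern prior
  (≈ 0.1), which leaves the network too far below the spike-initiation
  point for cue-driven completion.

## Plasticity of the associative pathway

### Spike-based BCPNN

Each plastic synapse runs two trace banks — fast (τ_z = 5 ms) and slow
(τ_z = 100 ms), matching the two receptor components, each with its own
weight gain — sharing the slow probability stage τ_p = 15 s:

    τ_z dZ/dt  = (spike drive) − Z + ε
    τ_p dP_i/dt  = κ (Z_i − P_i)        (same for P_j)
    τ_p dP_ij/dt = κ (Z_i Z_j − P_ij)
    w_ij = w_gain ln( P_ij / (P_i P_j) ),   β_j = β_gain ln P_j

Spikes enter Z as an instantaneous increment 1/(f_max τ_z) — the
integral-equivalent of a 1 ms rectangular pulse of height 1/(f_max·t_spike)
— so sustained firing at f_max = 25 Hz gives a time-averaged Z of ε + 1 ≈ 1
and, in general, the time-averaged Z is ε + f/f_max.  Traces start at the
naive prior (P_i = P_j = ε = 0.0026, P_ij = ε²), so initial weights are
exactly zero and bindings are learned, not preloaded.  Discretization is
exact per step (exponential decay between events, exponential-Euler
relaxation of P), so κ = 0 freezes the plastic state bit-exactly; the suite
verifies that the compiled network kernel and the plain reference integrator
produce identical traces on identical spike trains.  In the network the P
stage is relaxed every 1 ms (the exact factor 1 − e^(−κ·Δ/τ_p)); with
τ_p = 15 s the coarser grid is numerically irrelevant, and it is exposed as
`SimParams.p_update_interval`.

κ is gated per synapse and per cell at three levels (0 frozen, 1 normal,
2 boost) and stays at 1 through encoding and recall unless an experiment
overrides it.  Boosting κ during one pairing's encoding epoch strengthens
that pairing's coactivation trace and its cells' bias.  Note a limitation:
from the naive-prior start, the boosted pairing's *log-odds weight* ends
lower, not higher — all three probability estimates inflate together and
the prior product in the denominator grows faster than the joint — so the
retention advantage in this implementation is carried by the coactivation
trace and the excitability, not by the weight itself.

### Multiplicative STDP (comparison rule)

The associative pathway can instead run nearest-neighbor multiplicative
STDP: weights are kept normalized in [0, 1], scaled on delivery by per-
component maxima (13.5 / 3.5 nS), and updated per pairing with
Δt = t_post − (t_pre + delay):

    Δw = +λ (1−w) e^(−|Δt|/τ₊)   if Δt ≥ 0,
    Δw = −λ α w e^(−|Δt|/τ₋)     otherwise

with λ = 0.01, α = 1.2, τ± = 20 ms (α τ₋/τ₊ > 1 guarantees net depression
over a symmetric lag window — verified numerically).  The printed branch
condition involving the transmission delay is read as a typographical
artifact of the delay already being inside Δt; the literal reading is
available behind `StdpParams.branch_at_delay`.  There is no bias plasticity
in the STDP condition.

## Task protocol and detection

A trial is: 250 ms noise-only settling; one 250 ms / 500 Hz encoding epoch
per item-context pairing (both patterns driven together; order shuffled per
trial by default) at 500 ms interstimulus intervals; a 1 s delay at which
the background switches from the encoding rate (650 Hz) to the recall rate
(450 Hz); then 50 ms / 400 Hz cues of items or contexts, one 500 ms scoring
window each.  The default association map binds four items to 3, 2, 1 and 4
of ten distinct contexts (each context used exactly once).  Background noise
is a zero-mean pair of independent Poisson streams with opposing driving
potentials (+1.5 nS at 0 mV, 1.5 nS at −75 mV); the tabulated rates are
read as the rate of the pair summed, i.e. each generator runs at half the
tabulated rate.  The per-generator reading doubles the noise variance and
pushes the trained network into spontaneous free recall, consistent with
the reference model's note that ~40% more noise enters that regime.

Attractor activations are detected from the population rate of each
pattern's minicolumn in a designated sample hypercolumn (30 cells, HC 0): a
leaky filter e_t = (1 − ΔT/τ) e_{t−ΔT} + (spike count)/(τ·n_pop), τ = 40 ms,
ΔT = 1 ms, calibrated so a constant per-neuron rate f reads f in Hz, with a
10 Hz threshold, a 40 ms minimal duration and a 40 ms offset re-cross
guard.  The printed recursion (previous estimate multiplied by ΔT/τ)
discards 97.5% of the state per millisecond and cannot implement the
filter; it is kept behind a flag for comparison.  An item cue that
reactivates its item attractor scores know-like; if any associated context
attractor also activates inside the window it scores remember-like;
otherwise it is a miss.

## Scales, problem sizes, and what the desk-scale runs show

The reference scale is 12 HCs per network.  Experiment-level testing runs a
reduced 6-HC-per-network model (3840 cells, ≈ 1.8 M static and 130 k
plastic synapses; a full ~10.5 s trial simulates in under a minute on one
CPU), with the delivered recurrent conductance scaled up by the ratio of
reference to reduced expected same-pattern fan-in (≈ 2.0) — without this
compensation a downsampled attractor cannot complete from a cue (verified).
The plastic associative pathway keeps its native strength.

At this reduced scale, cued recall saturates: the calibrated operating
point makes item-cue completion and context retrieval reliable for all
association counts, so recall-rate curves are flat near 1.0 and the graded
recall percentages of the full-scale model are not reproduced here (the
context-cued direction is not saturated and does show graded retrieval).
What the desk-scale experiments do show, robustly over seeds, is the
synaptic semantization signature itself: post-encoding associative weight
distributions decrease monotonically with association count under BCPNN,
with the item cells' bias increasing in parallel (the Bayesian
weight/bias trade-off), while STDP weight means stay within 10% of each
other across counts.  The reduced seven-neuron microcircuit reproduces the
same contrast deterministically with continuous weight tracking.

The synthetic task generator emulates the trial structure, drive statistics
and association bookkeeping of the episodic experiment; it does not emulate
overlapping or hierarchical memory representations, behavioral timescales
beyond a dozen seconds, neuromodulatory dynamics beyond the κ gate, or any
statistical structure shared between memory objects — so passing tests
support the plasticity-level mechanism, not quantitative behavioral
predictions.

## Numerical and degenerate-input choices

* Exponential-upstroke argument capped at 16 before exp() (the cell is
  registered as spiking within the step far below that point).
* Delays are rounded to integer steps, floored at one step, and capped by
  the delivery ring length (the realized maximum delay).
* Poisson drive is realized as per-step Bernoulli events through exact
  geometric inter-event sampling (rate·dt ≤ 0.065 here, so the probability
  of a lost coincident second event is < 0.3%).
* Empty populations, unknown receptor labels, non-finite state, negative
  rates, inconsistent layouts and association maps raise errors rather than
  propagate.
* PSP measurements on an unconnected pair are impossible by construction:
  the harness takes explicit synapse lists.
* At most one spike per neuron per step (guaranteed by the 5 ms refractory
  period against dt = 0.1 ms).

## Known limitations

* Graded recall percentages, multi-cue recovery rates and the recall-level
  preferential-retention effect are full-scale, long-running experiments;
  the desk-scale acceptance surface covers their mechanisms (weights,
  traces, bias, scheduling) but not the printed percentages.
* The boosted pairing's log-odds weight decreases from a cold start (see
  above) — the weight-level preferential-retention claim does not hold under
  the naive-prior initialization.
* Baseline activity at the calibrated operating point is quiescent
  (≪ 1 Hz); the detection threshold is treated as absolute rather than as a
  multiple of measured baseline.
* No voltage-dependent NMDA block, single-compartment cells, and the
  subthreshold voltage course of AdEx is phenomenological.
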