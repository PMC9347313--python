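# semnet

A spiking cortical model of **episodic-memory semantization** — the gradual
decoupling of memory items from their episodic contexts — for computational
neuroscientists studying attractor memory and synaptic learning rules.

The model couples two modular attractor networks (an *Item* and a *Context*
network of adaptive exponential integrate-and-fire neurons, 7200 pyramidal
and 480 basket cells at reference scale) through a sparse plastic
associative pathway.  Items and contexts live in the networks as preloaded
(consolidated) cell assemblies; the associative pathway is learned online
during an episodic task in which each item is encoded together with one or
several contexts and later probed with brief cues.

The scientific core is the spike-based Bayesian-Hebbian (BCPNN) learning
rule.  Each plastic synapse keeps exponentially averaged estimates of pre-,
post- and co-activation (fast Z traces feeding slow P traces, τ_p = 15 s),
from which it computes a log-odds weight and each cell a log-prior bias:

    w_ij = w_gain · ln( P_ij / (P_i · P_j) ),      β_j = β_gain · ln P_j

Because the weight is normalized by the *marginal* activation estimates, an
item that appears in many different contexts grows its P_i and thereby
weakens **all** of its context bindings — semantization falls out of the
Bayesian bookkeeping.  A multiplicative nearest-neighbor STDP rule can be
swapped into the same pathway as the comparison condition: it only sees
pairwise spike timing, so its weights are independent of how many contexts
an item visits.  Tsodyks-Markram short-term plasticity (depression +
slow augmentation), distance-dependent conduction delays, basket-cell
winner-take-all inhibition and an EMA-based attractor-activation detector
complete the model.  See `docs/methods.md` for the full account.

## Worked example: the microcircuit contrast

The reduced seven-neuron model tracks single synapses continuously while two
item neurons form two and three context associations:

```
$ semnet micro --rule bcpnn --out traj_bcpnn.csv
synapse 0->2 (2 associations): final slow-component weight 0.1164 nS
synapse 1->4 (3 associations): final slow-component weight 0.0879 nS

$ semnet micro --rule stdp --out traj_stdp.csv
synapse 0->2 (2 associations): final slow-component weight 0.9860 nS
synapse 1->4 (3 associations): final slow-component weight 0.9860 nS
```

Under BCPNN the item trained in three contexts converges on a ~25% weaker
binding than the item trained in two — every epoch spent with another
context raises the item's activation estimate and decays the pair's
coactivation trace.  Under STDP the two synapses end exactly equal: a
synapse is simply untouched while its item fires with other contexts.
`traj_*.csv` holds the full weight trajectories (time, synapse, fast and
slow components).

## Full network experiments

```
semnet run --variant item-cued   --rule bcpnn --trials 20 --seed 1 --out out/bcpnn
semnet run --variant item-cued   --rule stdp  --trials 20 --seed 1 --out out/stdp
semnet run --variant context-cued --rule bcpnn --trials 20 --seed 1 --out out/ctx
semnet run --variant multi-cue    --rule bcpnn --trials 20 --seed 1 --out out/multi
semnet run --variant boost        --rule bcpnn --trials 20 --seed 1 --out out/boost
```

Each run writes `recall.csv` (mean cued-recall per association count with
Bernoulli SDs), `weights.csv` / `weights_summary.csv` (post-encoding
associative weight distributions by association count and direction),
`params.yaml` and a JSON manifest; `--keep-rasters` adds two-column spike
rasters per trial.  `--hc 6` runs the reduced desk-scale network (a ~10.5 s
trial simulates in under a minute; the reference 12-HC scale takes several
minutes per trial).  At desk scale the associative weight distributions
show the semantization gradient robustly while cued recall saturates near
ceiling; the graded recall percentages belong to the full-scale model
(`docs/methods.md`, "Scales").

Library use mirrors the CLI:

```python
from semnet import ExperimentConfig, build_network, reduced_params, run_experiment

net = build_network(reduced_params(n_hc=6), seed=1)
table, trials = run_experiment(net, ExperimentConfig(variant="item-cued",
                                                     rule="bcpnn"), n_trials=10)
print(table)   # recall by association count
```

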