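# morphodyn

Morphospace disparity and Bayesian evolutionary-rate analysis for fossil
clades, in Python.

Deep-time studies of ecomorphology — skull and jaw shape in crocodylomorphs
being the textbook case — share one workflow: digitise 2D landmarks,
superimpose them, ordinate the shapes into a morphospace, time-calibrate a
supertree of mostly extinct taxa against the fossil record, measure how
morphological variety (disparity) waxed and waned through time, and ask
whether the tempo of shape evolution was homogeneous or punctuated by
clade-specific bursts. `morphodyn` implements that entire workflow as a
tested library, together with a synthetic-data generator that produces
trees, traits, landmarks and fossil occurrence ranges with *known ground
truth*, so every stage can be validated by recovering what was planted.

It is aimed at palaeobiologists and methods developers who want the
standard analyses (normally scattered across `geomorph`, `paleotree`,
`dispRity` and BayesTraits) scriptable, seeded, and checkable in one place.

## What's inside

| stage | module | core method |
| --- | --- | --- |
| synthetic truth | `morphodyn.simulate` | birth–death trees with extinct tips, clade rate regimes, Brownian traits mapped to landmarks, FAD/LAD ranges |
| morphometrics | `morphodyn.procrustes`, `.ordination`, `.landmarks` | GPA with sliding semilandmarks (bending-energy criterion), tangent-space PCA, broken-stick axis selection, TPS I/O |
| time-calibration | `morphodyn.timescale` | uniform polytomy resolution, Uniform[LAD, FAD] tip ages, `equal` / `mbl` / cal3-style dating, 100-tree ensembles |
| disparity | `morphodyn.disparity` | MPD, MST length, alpha-shape volumes, Foote partial disparity, bootstrap CIs, partial rarefaction, Brownian ancestral states, time-slicing |
| rates | `morphodyn.rates` | multivariate variable-rates Brownian model: pruning likelihood, reversible-jump MCMC over branch/clade shifts, stepping-stone marginal likelihoods, Bayes factors, consensus rate trees, rates through time |
| orchestration | `morphodyn.pipeline`, `morphodyn.cli` | one-config end-to-end runs with a checksummed, bit-reproducible manifest |

The central model: traits (morphospace scores) evolve by Brownian motion
with per-trait base variance σ²ⱼ (per Myr); each branch carries a rate
scalar r — the product of shifts scoped to single branches or whole clades
— so an increment over duration t has variance σ²ⱼ·r·t. The
reversible-jump sampler explores the number, placement and size of shifts;
model fit is compared by 2·Δlog marginal likelihood (> 10: very strong
support for heterogeneous rates).

## Worked example: recover a planted 10× rate shift

```python
import pandas as pd
from morphodyn import (ChainConfig, bayes_factor, make_world,
                       rjmcmc_variable_rates, stepping_stone)

world = make_world(n_tips=48, shift_scalar=10.0, seed=2)   # ground truth
traits = pd.DataFrame({t: v for t, v in world.tip_traits.items()}).T

config = ChainConfig(iterations=100_000, burn_in=20_000, thinning=100,
                     seed=0, n_stones=20, stone_iterations=2_000)
posterior = rjmcmc_variable_rates(world.tree, traits, config)

node, scalar = world.shift_nodes[0]
print(posterior.clade_background_ratio(node))
bf = bayes_factor(stepping_stone(world.tree, traits, "variable", config),
                  stepping_stone(world.tree, traits, "homogeneous", config))
print(bf)
```

Running this (it is `examples/05_variable_rates.py`) prints:

```
planted: scalar 10 on 14 tips
posterior mean shift count: 11.2
clade/background mean-scalar ratio: 12.6  (planted 10)
log ML variable 50.6 vs homogeneous 9.7 -> Bayes factor 81.8 ( > 10 is very strong)
```

The posterior mean scalars inside the planted clade exceed the background
by ~12×, close to the simulated 10×, and the Bayes factor of ~82 far
exceeds the conventional "very strong" threshold of 10 — the sampler both
localises the shift and decisively rejects rate homogeneity. On worlds
simulated *without* a shift the same comparison yields negative Bayes
factors (no spurious heterogeneity).

The other `examples/` scripts walk the remaining capabilities — world
simulation, GPA + PCA morphospace, dating ensembles, and disparity through
time — each printing its numbers with a line on what they mean. A full
pipeline run is one command:

```sh
morphodyn all --config examples/pipeline.yaml
morphodyn report --out-dir morphodyn_out
```

## Documentation

`docs/methods.md` describes the models, priors, defaults and numerical
choices in detail, what the synthetic generator does and does not emulate,
and the package's known limitations.
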