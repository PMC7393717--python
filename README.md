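# modulevo

Comparative morphometrics of skeletal landmark data: generalized Procrustes
analysis, maximum-likelihood modularity model selection on landmark
correlation matrices, stochastic character mapping of a binary habitat
character, and phylogenetic comparisons of disparity and multivariate
Brownian evolutionary rates.

## Who this is for

Evolutionary morphologists asking how trait covariation (modularity and
integration) relates to shape divergence across an ecological gradient — for
example, cichlid feeding bones in populations partitioned between shallow
and deep habitats.  The package takes 3D landmark configurations (fixed
landmarks plus semilandmark curves), specimen metadata, a sample of rooted
ultrametric trees representing posterior phylogenetic uncertainty, and a set
of landmark-partition hypotheses, and carries the whole analysis chain from
raw coordinates to model-selection frequencies, transition counts, rate
ratios, and disparity tests.  A first-class synthetic-data generator
produces trees, habitat histories, and modular landmark datasets with the
covariance structure the analyses assume, so every stage is testable without
access to original scan data.

## The models at the core

**Shape.** Configurations of k landmarks are superimposed by generalized
Procrustes analysis (centering, scaling to unit centroid size
CS = sqrt(sum_i ||x_i − x̄||²), and iterative optimal rotation).  Allometry is
removed by regressing shape on centroid size and keeping residuals;
r² = SS_model/SS_total with a permutation p-value.

**Modularity (EMMLi).**  Each landmark is one trait; the correlation between
landmarks i and j is the absolute congruence coefficient of their 3D
deviation vectors across observations.  A modularity model pools the
off-diagonal correlations — within modules and between modules, separately
(`sep`) or shared (`same`) — and scores each pool by a Gaussian likelihood on
Fisher-z transformed correlations with SE 1/sqrt(n−3), maximizing the pooled
ρ over the grid {0, 0.01, …, 0.99}.  Models are ranked by
AICc = −2 logL + 2K + 2K(K+1)/(n_c − K − 1), with K = (#ρ pools) + 1 and n_c
the number of unique correlations; "model likelihood" is exp(−ΔAICc/2) and
the posterior probability is the Akaike weight.  To respect phylogeny the
correlations are computed from phylogenetic independent contrasts of OTU
mean shapes, once per tree across the whole posterior sample, giving
selection *frequencies* rather than a single verdict.

**Habitat transitions.**  A two-state Mk model (ER or ARD) is fitted by
maximum likelihood on each tree; stochastic character maps are drawn from
the joint conditional distribution of node states with endpoint-conditioned
CTMC paths along branches, and directional transition counts
(shallow→deep, deep→shallow) are averaged over maps and trees.

**Rates and disparity.**  The multivariate Brownian rate of a group is
σ²_mult = Σ‖C^(−1/2)(y_i − â)‖²/(n p); group differences are tested by
permutation of the phylogenetically whitened residuals, module differences by
parametric bootstrap under a common rate that preserves the observed
among-trait correlation.  Disparity is Procrustes variance (mean squared
distance from the group mean shape), on ordinary residuals or on
phylogenetic-GLS residuals of shape on size.  Group shape differences are
tested by MANOVA on PC scores — ordinary, or with a Brownian-simulation null
for the phylogenetic version.

## Worked example

```python
import numpy as np
from modulevo import synthgen, morpho, emmli, phylo

cfg = synthgen.SimulationConfig(seed=7, n_trees=100)   # 22 OTUs, 109 landmarks
tree = synthgen.simulate_tree(cfg)
trees = synthgen.simulate_tree_sample(tree, cfg)       # posterior-like ensemble
dataset = synthgen.simulate_shapes(tree, cfg)          # 66 specimens

alignment = morpho.gpa(dataset)
allom = morpho.allometry_anova(alignment, n_perm=999, seed=1)
print(f"allometry: r^2 = {allom.r_squared:.3f}, p = {allom.p_value:.4f}")

means = morpho.otu_means(allom.residual_dataset)
assign = synthgen.generating_partition(cfg)
generating = emmli.PartitionHypothesis("functional",
                                       tuple(f"M{m}" for m in assign))
null = emmli.PartitionHypothesis("null", ("all",) * cfg.n_landmarks)
ens = emmli.emmli_over_trees(means, trees, [generating, null])
for name, f in sorted(ens.selection_frequency.items(), key=lambda kv: -kv[1]):
    print(f"{name}: selected in {f:.0%} of 100 trees")

tips, truth = synthgen.simulate_habitat(tree, cfg)
summary = phylo.average_transitions(trees[:50], tips, seed=2)
print(f"habitat transitions: mean {summary['mean_total']:.1f} "
      f"(shallow->deep {summary['mean_shallow_to_deep']:.1f}, "
      f"deep->shallow {summary['mean_deep_to_shallow']:.1f})")
```

Output:

```
allometry: r^2 = 0.266, p = 0.0010
functional.sep.Mod+sep.between: selected in 100% of 100 trees
habitat transitions: mean 14.6 (shallow->deep 6.9, deep->shallow 7.7)
```

Reading this: shape depends measurably on size (r² = 0.27, significant at
the permutation level), so residuals are carried forward; across all 100
trees of the ensemble the six-module generating partition — with separate
within- and between-module ρ — beats the no-modularity null; and the fitted
Mk model plus stochastic maps put the average number of habitat switches at
about 15 across the tree, split roughly evenly between directions (the true
simulated history had 11; see `docs/methods.md` on the upward bias of mapped
counts for saturated characters on small tip samples).

The same workflow is available from the shell:

```sh
modulevo simulate --config sim.yaml --out data/ --seed 7
modulevo run --config study.yaml --out results/ --seed 7
```

`modulevo run` writes one delimited table per analysis, a `report.txt`
summary, and a `manifest.json` recording inputs, settings, and the per-stage
seeds derived from the master seed; identical config + seed reproduce the
bundle byte for byte.

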