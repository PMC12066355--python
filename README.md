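# hybridbarriers

Analyses of reproductive barriers between naturally hybridizing swordtail
fishes (*Xiphophorus birchmanni* × *X. cortezi*), built around the genomic
signatures such barriers leave in a bimodal hybrid population:

* **Hybrid index and bimodality.** From per-site ancestry calls (0/1/2 copies
  of the *X. cortezi*-derived allele) the hybrid index of individual *i* is
  *h_i* = Σ calls / (2 · # non-missing sites). Population-level bimodality is
  tested with Hartigan's dip statistic *D* — the sup-norm distance between
  the empirical CDF and the nearest unimodal CDF — with a uniform-null
  bootstrap p-value.
* **Assortative mating from mother/embryo pairs.** An embryo's index is the
  mean of one maternal and one paternal gamete fraction, so the difference
  Δ = *h*(embryo) − *h*(mother) estimates half the father−mother difference.
  Cross-cluster matings predict |Δ| ≈ (μ_B − μ_A)/2 ≈ 0.37 for the observed
  clusters (0.019 ± 0.006 vs 0.757 ± 0.017); within-cluster matings predict
  |Δ| ≈ 0. An assortment strength *a* (probability a female mates within her
  own cluster) is fit by simulating panels matched to the observed design.
* **Segregation distortion in F2 crosses.** Unselected F2s have expected
  genotype frequencies (¼ CC, ½ BC, ¼ BB) and mean ancestry 0.5 everywhere;
  viability selection with fitnesses (1, 1−*hs*, 1−*s*) for (CC, BC, BB)
  distorts this. The scan compares per-marker mean ancestry against a
  simulated genome-wide (family-wise) 95% envelope and delimits distorted
  intervals by the decay of ancestry *R*² around the peak marker.
* **Rejection ABC for selection strength.** (*s*, *h*) ~ Uniform(0,1)²;
  cohorts of surviving F2s are drawn from the post-selection frequencies
  *f*'_g ∝ *f*_g *w*_g; draws whose summary statistics (mean *X. birchmanni*
  ancestry and carrier count at the locus) fall within 5% of the observed
  values form the posterior, summarised by a boundary-reflected KDE MAP and
  a central 95% credible interval.
* **Mitochondrial divergence dating.** Divergence-without-gene-flow is
  simulated as Poisson(2μ*T*L) substitutions on L sites (distinct-site
  counting), and divergence times are estimated by rejection ABC on the
  observed pairwise divergence.

Every input can be generated synthetically (`hybridbarriers.synthetic_data`),
so the full pipeline runs and is tested without any sequencing data.

## Worked example

```python
import numpy as np
from hybridbarriers import (
    ClusterModel, MatingModel, simulate_population, dip_test,
    simulate_mother_embryo_panel, default_genome, pair_differences,
    SelectionParams, post_selection_frequencies, draw_cohort, abc_reject,
)

clusters = ClusterModel()          # observed: 0.019±0.006 / 0.757±0.017, 62:38

# 1. bimodality of 306 sampled adults
idx = simulate_population(clusters, 306, seed=1)
D, p = dip_test(idx, n_boot=1000, seed=2)
print(f"dip D={D:.3f}, p={p:.4f}")

# 2. cross-cluster mating expectation
panel = simulate_mother_embryo_panel(
    clusters, MatingModel("cross_cluster"), 2000, 1, default_genome(), seed=3)
print(f"mean |embryo-mother| = {100*np.abs(pair_differences(panel)).mean():.1f}%")

# 3. selection at a lethal-recessive incompatibility in 163 F2 adults
counts = draw_cohort(post_selection_frequencies(SelectionParams(0.995, 0.027)),
                     163, seed=4)
post = abc_reject(counts, 163, n_draws=200_000, seed=5,
                  separate_carrier_counts=True)
print(f"MAP s={post.map_s:.3f}, 95% CI {post.ci_s[0]:.3f}-{post.ci_s[1]:.3f}")
```

Output:

```
dip D=0.165, p=0.0000
mean |embryo-mother| = 36.9%
MAP s=0.962, 95% CI 0.874-0.991
```

The dip ≈ 0.17 with p ≈ 0 says the simulated population is strongly bimodal
at the study's sample size; 36.9% is the expected mother/embryo ancestry gap
for a cross-cluster mating (so observed gaps near zero indicate assortative
mating); and the ABC recovers near-complete recessive selection (s ≈ 1)
against *X. birchmanni* ancestry at the incompatible locus.

A command-line interface mirrors the library:

```bash
hybridbarriers stats chisq --counts 0,0,33
hybridbarriers run demo-population --seed 1 --out results/
hybridbarriers abc-selection --counts 54,109,0 --seed 1
```

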