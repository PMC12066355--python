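# Methods

This note documents the models behind `hybridbarriers`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Ancestry model and data contract

Ancestry at an ancestry-informative site is the number of *X. cortezi*-derived
alleles (0 = homozygous *X. birchmanni* "BB", 1 = heterozygous "BC", 2 =
homozygous *X. cortezi* "CC"), with missing (`NA`) as a first-class state
that is never imputed. Hard calls are produced from posterior triples
(p_BB, p_BC, p_CC) by strict thresholding: the call whose posterior strictly
exceeds the cutoff (default 0.9), otherwise missing. A state tying the
cutoff exactly is treated as not exceeding it — the natural reading of a
">cutoff" rule. Marker positions are 1-based in files; every exported
interval is BED-style 0-based half-open.

The hybrid index is Σcalls / (2·#non-missing). It is undefined (an error,
never silently 0) when every call is missing.

## Synthetic genome and crossover model

The default genome is 24 chromosomes × 25 Mb × 1.0 Morgan with 500 evenly
spaced markers per chromosome. The karyotype matches *Xiphophorus* (24
chromosomes); 1 Morgan per chromosome makes an F2 carry about two crossovers
per chromosome (one per gamete), the relevant recombination scale for
admixture-LD in second-generation hybrids. Marker density (one per 50 kb) is
far below the real ~10⁶ informative sites but far above the scale on which
F2 ancestry varies, so per-individual hybrid indices are essentially exact.

Crossovers per gamete and chromosome are Poisson with mean equal to the
genetic length; breakpoints are uniform on physical length; there is no
interference. The starting haplotype is equiprobable and alternates at each
breakpoint. Genetic lengths come from the marker map (an override tuple on
`CrossoverModel` replaces them, e.g. 0 Morgans for unbroken transmission).

## Founder genomes for population members

Wild individuals are represented as segmental ancestry mosaics. Each
haplotype is cut by Poisson switch points at rate 2p(1−p)·g per Morgan —
the expected junction density after g generations of recombination at
admixture proportion p — and each segment is *X. cortezi* with probability
p, the individual's target hybrid index drawn from its cluster. The default
g = 40 reflects the population's documented age (bimodality stable for
roughly 40 generations). This gives gametes whose expected ancestry equals
the parent's index while carrying realistic finite-genome segregation
variance; that variance is what sets the spread of within-cluster
mother/embryo differences, and hence the safety margin of the cross-cluster
classification threshold.

A deliberate simplification: drawing the target index from the cluster
distribution *and* adding mosaic sampling noise slightly inflates the
realized between-individual spread relative to the printed cluster SDs. The
inflation (~1 percentage point of index SD) is negligible against the
~37-point cluster separation that all classification quantities depend on.

## Two-cluster population model

Hybrid indices are drawn from a two-component truncated-normal mixture,
defaulting to the observed clusters: 0.019 ± 0.006 (weight 0.62) and
0.757 ± 0.017 (weight 0.38). Truncation to [0, 1] is by rejection; SD = 0 is
allowed and degenerates to point masses. At n = 306 this model produces dip
statistics of ~0.16-0.19 — bimodality is unambiguous at the study's sample
size.

## Mating models and mother/embryo panels

One father per brood (multiple paternity is not modelled — inference
operates on the same brood-level signal as the underlying data). The
father's cluster is drawn by one scalar assortment strength a: with
probability a he is constrained to the mother's cluster, otherwise drawn by
cluster frequency. a = 0 is random mating, a = 1 complete assortative
mating; a third mode forces the opposite cluster, used to compute the
cross-cluster expectation (~36.9% mean |embryo − mother| difference; the
analytic midparent value is (0.757 − 0.019)/2 = 0.369).

Pairs are classified cross-cluster when |embryo − mother| exceeds
(μ_B − μ_A)/4 ≈ 0.1845, the midpoint between the within-cluster (≈0) and
cross-cluster (≈0.369) expectations — more than eight within-cluster
standard deviations from either, on the default genome.

The mating fit estimates, per strength on a grid, the per-brood probability
of being classified cross from simulated panels matched to the observed
design (same mothers, same embryos per mother), then scores the observed
number of cross broods with a Binomial(n_mothers, p̂) likelihood. Using the
analytic binomial on top of the simulated p̂ lets the fit resolve
likelihoods far below 1/n_sims (e.g. ~10⁻¹⁴ for zero cross broods out of 49
under random mating, where p̂ ≈ 0.47).

Pedigree classification of intermediate individuals simulates the
hybrid-index distribution of five scenarios — offspring of two cluster-A
parents, two cluster-B parents, an A×B pair (F1-type), an F1-type × A
backcross (BC1), and two F1-type parents (a third-generation, F2-like
genotype, the "gen3-cross" class) — and weights scenarios by the observed
index's Gaussian-KDE density under each, normalised (uniform prior over
scenarios).

## F2 cohorts and viability selection

An F2 is the union of two independent F1 gametes; since F1s are heterozygous
everywhere, gamete ancestry equals the crossover haplotype-choice process.
Viability selection at each configured locus multiplies survival by
(1, 1−hs, 1−s) for genotype (CC, BC, BB); multi-locus selection is
multiplicative and independent (loci are analysed one at a time downstream).
Cohorts are redrawn until the requested number of survivors is reached.

## Segregation-distortion scan

Per-marker mean ancestry is compared against a family-wise envelope: per
simulated unselected cohort, the genome-wide minimum and maximum of
per-marker means are recorded; the envelope is the (α/2, 1−α/2) quantile
pair of those extrema (default α = 0.05, 1000 replicates). Per-replicate
extrema rather than per-marker quantiles control the genome-wide error rate,
which is what a "genome-wide significance threshold" means; calibration is
verified empirically (fraction of fresh null cohorts with any flag ≈ α).

Flagged markers are merged into intervals with a gap tolerance of one
marker; the most extreme marker is the peak. Intervals of interest are then
delimited by LD: markers are thinned to the first per 50-kb window (any
deterministic rule is equivalent at F2 admixture-LD scale), *R*² is the
squared Pearson correlation of 0/1/2 codes over pairwise-complete
individuals (unphased dosage codes; no EM phasing), and the walk outward
from the peak stops at the first thinned marker with *R*² < 0.8, without
re-entry.

## Rejection ABC for (s, h)

Priors are Uniform(0,1) on both s and h. Each draw simulates one multinomial
cohort of n survivors (default n = 163) from the post-selection frequencies
and reduces it to (i) mean *X. birchmanni* ancestry at the locus and (ii)
the carrier count. "Within 5% of the observed data" is implemented as a
relative tolerance per statistic, both required; an observed value of 0
demands an exact simulated 0 (a relative band around 0 is empty). The
carrier statistic defaults to the single combined count n_BC + n_BB; a
config switch (`separate_carrier_counts=True`) matches n_BC and n_BB
individually instead. The phrase defining the statistic admits both
readings; the combined count is the more literal one, but when the observed
cohort contains zero BB adults the separate-count variant is much stricter
on weak selection (any simulated BB survivor rejects the draw) and produces
the sharper credible intervals characteristic of near-lethal recessive
incompatibilities. Both are first-class; tests cover both.

Posterior summaries: MAP from a Gaussian-KDE (Silverman bandwidth) evaluated
on a 1001-point grid with the sample reflected at both support boundaries —
without reflection, a mode at s = 1 (or h = 0) is biased inward — and a
central 95% credible interval from the 2.5/97.5 percentiles. Default
2×10⁵ draws runs in seconds and leaves hundreds to thousands of acceptances
at 5% tolerance for study-scale observations; fewer than 50 acceptances is
an error advising more draws rather than a silent noisy summary.

## Mitochondrial divergence and dating

Divergence-without-gene-flow over T generations puts Poisson(2μTL)
substitutions on L sites uniformly with replacement; divergence is the
distinct-site fraction. This saturates correctly at high 2μT but applies no
multiple-hit correction beyond site collision — at the <1% divergences of
interest the correction is second-order, and μ, L and the prior are
configuration, not asserted constants (defaults: μ = 10⁻⁸ per site per
generation, L = 16,000 — a placeholder mitogenome scale — prior
T ∈ [10⁴, 10⁶]). The time ABC accepts draws within a relative tolerance of
the observed divergence and summarises like the selection ABC, rescaled to
the prior range.

## Behavioural statistics

Strength of preference is (t_c − t_b)/(t_c + t_b) ∈ [−1, 1] (positive =
preference for the *X. cortezi* stimulus); trials where the female spent
strictly more than 80% of her time on one side are discarded before
analysis. Deviations from the null of 0 use one-sided Wilcoxon signed-rank
tests: scores tying the null are dropped, the exact distribution is used for
n ≤ 25 with untied ranks, otherwise the normal approximation with tie
correction (delegated to scipy; conventions match R's `wilcox.test`). The
two-sided exact binomial test (sex-ratio test) uses the minimum-likelihood
convention: the sum of all outcome probabilities not exceeding that of the
observed count.

## Dip statistic

Implemented from the greatest-convex-minorant / least-concave-majorant
construction (Hartigan & Hartigan's algorithm): iteratively shrink a
candidate modal interval until the larger of the empirical deviations from
the convex fit below and the concave fit above it stops improving. The
returned D is in count units / 2n; a sample of n distinct values has
D ≥ 1/(2n), and two equal point masses give the maximum 0.25. The test
p-value is the fraction of uniform(0,1) bootstrap samples of the same size
with dip ≥ observed (the dip is location-scale invariant, so the uniform
null is the standard calibration; the reference distribution depends only on
n). An independent linear-programming oracle — exact minimax fit over
unimodal CDFs with atoms allowed at the mode — verifies the construction on
every small grid sample in the test suite.

## Reproducibility and problem sizes

Every stochastic function takes a seed or Generator; workflows derive a
per-stage stream from (global seed, stage label) via `SeedSequence`, so
stages are independently reproducible. Test and acceptance problem sizes are
the study's own (n = 306 adults, n = 163 F2s, 49 mothers / 101 embryos,
1000-replicate envelopes, 2×10⁵ ABC draws); unit tests use a 4-chromosome
miniature genome where only the mechanism, not the scale, is under test.

## What synthetic data do and do not show

The generators reproduce the *structure* the analyses rely on — bimodal
clusters, Mendelian F2 segregation with admixture LD, midparent embryo
expectations with finite-genome variance, locus-specific viability
selection, call-level noise. They do not emulate read-level error
processes, reference bias, the empirical distribution of informative-site
density, linked selection, or multiple paternity. Passing tests therefore
demonstrate that the inference machinery is correct and calibrated under
its stated model, not that the model captures every property of the real
sequencing data.

## Known limitations

* Selection is viability-only and per-locus; two-locus (nuclear-nuclear)
  incompatibility selection is out of scope and would be underestimated by
  the single-locus model.
* The ABC is plain rejection sampling; no regression adjustment or SMC.
* The divergence model ignores ancestral polymorphism, so very recent
  divergence times are biased low relative to a coalescent treatment.
* `fit_mating_model` resolves assortment strength only as finely as the
  brood-level cross/within signal allows; with ~49 broods, strengths above
  ~0.9 are barely distinguishable from 1.
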