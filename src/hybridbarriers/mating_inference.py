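"""Inference of mating patterns from mother/embryo ancestry pairs.

A pregnant female's embryos carry one maternal and one paternal gamete, so
the embryo-minus-mother hybrid-index difference estimates half the father-
minus-mother difference.  Within-cluster matings give differences near zero;
cross-cluster matings give differences near (mean_B - mean_A)/2 ~ 0.37 for
the observed clusters.  This module classifies pairs, fits an assortative-
mating strength to the observed number of cross-cluster matings by
simulation, and classifies intermediate-ancestry individuals into recent
pedigree scenarios by simulating each scenario's hybrid-index distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ancestry_core import MarkerMap
from .synthetic_data import (
    ClusterModel,
    CrossoverModel,
    MatingModel,
    MotherEmbryoPanel,
    _crossover_choice,
    _founder_switch_rate,
    _mosaic_haplotypes,
    default_genome,
    simulate_mother_embryo_panel,
)

__all__ = [
    "PEDIGREE_CLASSES",
    "MatingFit",
    "pair_differences",
    "default_cross_threshold",
    "classify_cross_cluster",
    "fit_mating_model",
    "classify_recent_pedigree",
    "simulate_pedigree_class",
]

#: Recent-generation pedigree scenarios for intermediate-ancestry individuals.
PEDIGREE_CLASSES = (
    "within-cluster-A",
    "within-cluster-B",
    "F1-cross-cluster",
    "BC1-to-A",
    "gen3-cross",
)


def pair_differences(pairs: Iterable[tuple[float, float]] | MotherEmbryoPanel) -> np.ndarray:
    """Signed embryo - mother differences, order preserved."""
    if isinstance(pairs, MotherEmbryoPanel):
        return pairs.differences()
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("pairs must be a nonempty sequence of (mother, embryo) values")
    return arr[:, 1] - arr[:, 0]


def default_cross_threshold(model: ClusterModel) -> float:
    """Midpoint between the within-cluster (~0) and cross-cluster
    ((mean_B - mean_A)/2) expectations of |embryo - mother|."""
    sep = abs(model.mean_b - model.mean_a)
    if sep == 0.0:
        raise ValueError("degenerate cluster model: equal cluster means")
    return sep / 4.0


def classify_cross_cluster(
    pairs: Iterable[tuple[float, float]] | MotherEmbryoPanel,
    model: ClusterModel,
    threshold: float | None = None,
) -> np.ndarray:
    """Label each pair 'cross' (True) when |embryo - mother| exceeds the threshold.

    The inequality is strict: a difference exactly at the threshold counts as
    within-cluster.
    """
    thr = default_cross_threshold(model) if threshold is None else threshold
    if thr <= 0:
        raise ValueError("threshold must be > 0")
    return np.abs(pair_differences(pairs)) > thr


@dataclass(frozen=True)
class MatingFit:
    """Per-strength likelihood of the observed cross-cluster mating count."""

    strengths: np.ndarray
    likelihoods: np.ndarray
    cross_probabilities: np.ndarray
    best_strength: float
    observed_cross: int


def fit_mating_model(
    pairs: Iterable[tuple[float, float]] | MotherEmbryoPanel,
    model: ClusterModel,
    strengths: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_sims: int = 200,
    embryos_per_mother: int | Sequence[int] | None = None,
    markers: MarkerMap | None = None,
    xo: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
    threshold: float | None = None,
) -> MatingFit:
    """Fit the assortative-mating strength to observed mother/embryo pairs.

    For every strength ``a`` on the grid, panels matched to the observed
    design (same number of mothers, same embryos per mother) are simulated to
    estimate the per-mating probability that a brood is classified
    cross-cluster; the likelihood of the observed number of cross-cluster
    matings is then Binomial(n_mothers, p_cross(a)).  One father per brood is
    assumed, so the mating (brood) — not the embryo — is the Bernoulli unit.
    """
    strengths = np.asarray(list(strengths), dtype=float)
    if strengths.size == 0:
        raise ValueError("strength grid must be nonempty")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = markers if markers is not None else default_genome()

    if isinstance(pairs, MotherEmbryoPanel):
        n_mothers = pairs.n_mothers
        epm = np.bincount(pairs.mother_of_embryo, minlength=n_mothers)
        diffs = pairs.differences()
        mother_of = pairs.mother_of_embryo
    else:
        arr = np.asarray(list(pairs), dtype=float)
        diffs = arr[:, 1] - arr[:, 0]
        if embryos_per_mother is None:
            # without an explicit design, treat each pair as its own brood
            epm = np.ones(arr.shape[0], dtype=np.int64)
        else:
            epm = (
                np.asarray(embryos_per_mother, dtype=np.int64)
                if not np.isscalar(embryos_per_mother)
                else np.full(arr.shape[0] // int(embryos_per_mother), int(embryos_per_mother))
            )
        n_mothers = epm.size
        mother_of = np.repeat(np.arange(n_mothers), epm)

    thr = default_cross_threshold(model) if threshold is None else threshold
    # a brood is cross-cluster when any of its embryos is classified cross
    obs_cross_brood = np.zeros(n_mothers, dtype=bool)
    np.logical_or.at(obs_cross_brood, mother_of, np.abs(diffs) > thr)
    observed_cross = int(obs_cross_brood.sum())

    likelihoods = np.empty(strengths.size)
    p_cross = np.empty(strengths.size)
    for i, a in enumerate(strengths):
        mating = MatingModel("assortative", float(a))
        cross_broods = 0
        total_broods = 0
        reps_remaining = n_sims
        while reps_remaining > 0:
            # simulate up to 50 design-replicates at a time inside one big panel
            reps = min(50, reps_remaining)
            reps_remaining -= reps
            epm_rep = np.tile(epm, reps)
            panel = simulate_mother_embryo_panel(
                model,
                mating,
                n_mothers * reps,
                epm_rep,
                markers,
                xo,
                rng,
            )
            sim_cross = np.zeros(n_mothers * reps, dtype=bool)
            np.logical_or.at(
                sim_cross, panel.mother_of_embryo, np.abs(panel.differences()) > thr
            )
            cross_broods += int(sim_cross.sum())
            total_broods += n_mothers * reps
        p = cross_broods / total_broods
        p_cross[i] = p
        likelihoods[i] = stats.binom.pmf(observed_cross, n_mothers, p)
    best = float(strengths[int(np.argmax(likelihoods))])
    return MatingFit(
        strengths=strengths,
        likelihoods=likelihoods,
        cross_probabilities=p_cross,
        best_strength=best,
        observed_cross=observed_cross,
    )


# ---------------------------------------------------------------------------
# Pedigree classification of intermediate-ancestry individuals
# ---------------------------------------------------------------------------

def _founder_haps(rng, p, mf, morgans, generations):
    lam = _founder_switch_rate(p, generations) * morgans
    return _mosaic_haplotypes(rng, p, mf, lam)


def simulate_pedigree_class(
    label: str,
    model: ClusterModel,
    n_sims: int,
    markers: MarkerMap | None = None,
    xo: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
    founder_generations: float = 40.0,
) -> np.ndarray:
    """Simulate the hybrid-index distribution of one pedigree scenario.

    Scenarios: offspring of two cluster-A parents; two cluster-B parents; a
    cross-cluster (A x B) pair ("F1"); a first-generation cross-cluster
    individual backcrossed to cluster A ("BC1"); and two first-generation
    cross-cluster individuals ("gen3", an F2-like third-generation genotype).
    """
    if label not in PEDIGREE_CLASSES:
        raise ValueError(f"unknown pedigree class {label!r}")
    markers = markers if markers is not None else default_genome()
    xo = xo or CrossoverModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    morgans = xo.morgans(markers)
    n = int(n_sims)

    def _cluster_targets(cluster_b: bool, size):
        mean = model.mean_b if cluster_b else model.mean_a
        sd = model.sd_b if cluster_b else model.sd_a
        vals = rng.normal(mean, sd, size)
        bad = (vals < 0) | (vals > 1)
        while bad.any():
            vals[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (vals < 0) | (vals > 1)
        return vals

    if label == "within-cluster-A":
        parents = (_cluster_targets(False, n), _cluster_targets(False, n))
    elif label == "within-cluster-B":
        parents = (_cluster_targets(True, n), _cluster_targets(True, n))
    else:
        parents = (_cluster_targets(False, n), _cluster_targets(True, n))

    total = np.zeros(n)
    m_total = markers.n_markers
    for ci in range(markers.n_chromosomes):
        sl = markers.chrom_slice(ci)
        mf = markers.pos[sl] / markers.length_bp[ci]
        mg = float(morgans[ci])
        # founder haplotypes for each simulated family
        hapA = [
            _founder_haps(rng, parents[0], mf, mg, founder_generations) for _ in range(2)
        ]
        hapB = [
            _founder_haps(rng, parents[1], mf, mg, founder_generations) for _ in range(2)
        ]

        def _gamete(h0, h1):
            choice = _crossover_choice(rng, n, mf, mg)
            return np.where(choice == 0, h0, h1)

        if label in ("within-cluster-A", "within-cluster-B", "F1-cross-cluster"):
            child = _gamete(*hapA) + _gamete(*hapB)
        elif label == "BC1-to-A":
            f1_0, f1_1 = _gamete(*hapA), _gamete(*hapB)  # the F1's two haplotypes
            a_new = [
                _founder_haps(rng, _cluster_targets(False, n), mf, mg, founder_generations)
                for _ in range(2)
            ]
            child = _gamete(f1_0, f1_1) + _gamete(*a_new)
        else:  # gen3-cross: offspring of two independent F1-type individuals
            f1a = (_gamete(*hapA), _gamete(*hapB))
            hapA2 = [
                _founder_haps(rng, _cluster_targets(False, n), mf, mg, founder_generations)
                for _ in range(2)
            ]
            hapB2 = [
                _founder_haps(rng, _cluster_targets(True, n), mf, mg, founder_generations)
                for _ in range(2)
            ]
            f1b = (_gamete(*hapA2), _gamete(*hapB2))
            child = _gamete(*f1a) + _gamete(*f1b)
        total += child.sum(axis=1) / 2.0
    return total / m_total


def classify_recent_pedigree(
    index: float,
    model: ClusterModel,
    markers: MarkerMap | None = None,
    xo: CrossoverModel | None = None,
    n_sims: int = 2000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Posterior weight of each pedigree scenario for an observed hybrid index.

    Each scenario's index distribution is simulated, the observed index's
    density under a Gaussian-kernel smooth of each simulated sample is
    evaluated, and densities are normalised across scenarios (uniform prior
    over scenarios).  Weights sum to 1.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    if not (0.0 <= index <= 1.0):
        raise ValueError("hybrid index must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    densities = {}
    for label in PEDIGREE_CLASSES:
        sample = simulate_pedigree_class(label, model, n_sims, markers, xo, rng)
        sd = sample.std(ddof=1)
        bw = max(0.9 * sd * sample.size ** (-0.2), 1e-4)
        z = (index - sample) / bw
        densities[label] = float(np.exp(-0.5 * z**2).mean() / (bw * np.sqrt(2 * np.pi)))
    total = sum(densities.values())
    if total == 0.0:
        # observed index is far outside every scenario; fall back to uniform
        return {label: 1.0 / len(PEDIGREE_CLASSES) for label in PEDIGREE_CLASSES}
    return {label: d / total for label, d in densities.items()}
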