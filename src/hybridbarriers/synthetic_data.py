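"""Generators for every input the pipeline consumes.

The module emulates the study system — a strongly bimodal hybrid population
between X. birchmanni and X. cortezi — so that every downstream stage can be
exercised without any sequencing data:

* a two-cluster hybrid population (near-pure X. birchmanni cluster at
  hybrid index 0.019 +/- 0.006 and an admixed cluster at 0.757 +/- 0.017,
  mixing ~62%/38%),
* F1/F2 genomes under a Poisson crossover model without interference,
* locus-specific viability selection on F2 cohorts,
* mother/embryo panels under parameterised mating models (random,
  partially/completely assortative, or forced cross-cluster), and
* call-level noise and missingness.

The default synthetic genome is 24 chromosomes of 25 Mb and 1.0 Morgan with
500 evenly spaced markers each, matching the Xiphophorus karyotype scale.

Founder genomes for population members are segmental ancestry mosaics: each
haplotype is cut by a Poisson number of switch points (rate
``2 p (1-p) * founder_generations`` per Morgan, the expected junction density
after ``founder_generations`` generations of recombination at admixture
proportion p) and each segment is X. cortezi with probability p.  A founder's
gamete therefore has expectation equal to the founder's hybrid index and the
finite-genome segregation variance that the mating-classification threshold
depends on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ancestry_core import MISSING, AncestryMatrix, MarkerMap
from .selection_abc import SelectionParams

__all__ = [
    "ClusterModel",
    "CrossoverModel",
    "MatingModel",
    "MotherEmbryoPanel",
    "CHAPULHUACANITO_CLUSTERS",
    "default_genome",
    "simulate_population",
    "simulate_gamete",
    "simulate_f2_cohort",
    "simulate_mother_embryo_panel",
    "add_call_noise",
    "write_panel",
]

#: Generations of recombination assumed for founder ancestry mosaics.
DEFAULT_FOUNDER_GENERATIONS = 40.0


@dataclass(frozen=True)
class ClusterModel:
    """Two-component description of a bimodal hybrid population.

    Cluster A is the near-pure X. birchmanni cluster, cluster B the admixed
    cluster; ``mix_a`` is the proportion of individuals in cluster A.
    Samples are truncated-normal on [0, 1] (reject and redraw).
    """

    mean_a: float = 0.019
    sd_a: float = 0.006
    mean_b: float = 0.757
    sd_b: float = 0.017
    mix_a: float = 0.62

    def __post_init__(self) -> None:
        for m in (self.mean_a, self.mean_b):
            if not (0.0 <= m <= 1.0):
                raise ValueError("cluster means must lie in [0, 1]")
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("cluster SDs must be >= 0")
        if not (0.0 < self.mix_a < 1.0) and self.mix_a not in (0.0, 1.0):
            raise ValueError("mixing proportion must lie in [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw n hybrid indices; returns (values, cluster labels 0=A, 1=B)."""
        cluster = (rng.random(n) >= self.mix_a).astype(np.int8)
        mean = np.where(cluster == 0, self.mean_a, self.mean_b)
        sd = np.where(cluster == 0, self.sd_a, self.sd_b)
        vals = rng.normal(mean, sd)
        bad = (vals < 0) | (vals > 1)
        while bad.any():  # truncate to [0, 1] by redraw
            vals[bad] = rng.normal(mean[bad], sd[bad])
            bad = (vals < 0) | (vals > 1)
        return vals, cluster


#: Cluster parameters observed in the Chapulhuacanito hybrid population.
CHAPULHUACANITO_CLUSTERS = ClusterModel()


@dataclass(frozen=True)
class CrossoverModel:
    """Poisson crossover model without interference.

    Crossover counts per gamete and chromosome are Poisson with mean equal to
    the chromosome's genetic length (Morgans, taken from the marker map unless
    overridden); breakpoints are uniform on physical length.
    """

    interference: str = "none"
    morgans_override: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.interference != "none":
            raise ValueError("only interference='none' is supported")

    def morgans(self, markers: MarkerMap) -> np.ndarray:
        if self.morgans_override is not None:
            m = np.asarray(self.morgans_override, dtype=float)
            if m.shape != (markers.n_chromosomes,):
                raise ValueError("morgans_override must have one entry per chromosome")
            if np.any(m < 0):
                raise ValueError("genetic lengths must be >= 0")
            return m
        return markers.length_morgans


@dataclass(frozen=True)
class MatingModel:
    """How a mother's mate is drawn with respect to ancestry cluster.

    ``kind='assortative'`` with strength ``a``: with probability ``a`` the
    father is constrained to the mother's own cluster, otherwise he is drawn
    by cluster frequency.  ``a = 1`` is complete assortative mating and
    ``a = 0`` reduces to random mating.  ``kind='random'`` is shorthand for
    a = 0.  ``kind='cross_cluster'`` forces the father into the opposite
    cluster (used to compute the cross-cluster expectation).
    """

    kind: str = "random"
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "assortative", "cross_cluster"):
            raise ValueError(f"unknown mating model kind {self.kind!r}")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("assortment strength must lie in [0, 1]")

    def father_clusters(
        self, mother_cluster: np.ndarray, mix_a: float, rng: np.random.Generator
    ) -> np.ndarray:
        n = mother_cluster.size
        random_draw = (rng.random(n) >= mix_a).astype(np.int8)
        if self.kind == "cross_cluster":
            return (1 - mother_cluster).astype(np.int8)
        if self.kind == "random":
            return random_draw
        constrained = rng.random(n) < self.strength
        return np.where(constrained, mother_cluster, random_draw).astype(np.int8)


def default_genome(
    n_chromosomes: int = 24,
    chrom_bp: int = 25_000_000,
    chrom_morgans: float = 1.0,
    markers_per_chrom: int = 500,
) -> MarkerMap:
    """Default synthetic genome: evenly spaced markers on equal chromosomes."""
    spacing = chrom_bp // markers_per_chrom
    pos_one = spacing * np.arange(markers_per_chrom, dtype=np.int64) + spacing // 2
    return MarkerMap(
        chroms=tuple(f"chr{i + 1}" for i in range(n_chromosomes)),
        chrom_index=np.repeat(np.arange(n_chromosomes), markers_per_chrom),
        pos=np.tile(pos_one + 1, n_chromosomes),
        length_bp=np.full(n_chromosomes, chrom_bp),
        length_morgans=np.full(n_chromosomes, chrom_morgans),
    )


# ---------------------------------------------------------------------------
# Vectorised segmental machinery
# ---------------------------------------------------------------------------

def _breaks(rng: np.random.Generator, n_seq: int, lam: np.ndarray | float):
    """Poisson(lam) break counts per sequence with uniform positions in [0,1)."""
    k = rng.poisson(lam, n_seq)
    return k, np.repeat(np.arange(n_seq), k), rng.random(int(k.sum()))


def _segment_index(seq: np.ndarray, frac: np.ndarray, mf: np.ndarray, n_seq: int) -> np.ndarray:
    """Per (sequence, marker) count of breaks left of the marker.

    ``mf`` is the markers' fractional physical position; a break at fraction b
    affects all markers with position > b.
    """
    m = mf.size
    iv = np.searchsorted(mf, frac, side="right")
    a = np.zeros((n_seq, m + 1), dtype=np.int32)
    np.add.at(a, (seq, iv), 1)
    return np.cumsum(a, axis=1)[:, :m]


def _crossover_choice(
    rng: np.random.Generator, n_gam: int, mf: np.ndarray, morgans: float
) -> np.ndarray:
    """(n_gam, m) haplotype chooser: equiprobable start, alternating at breaks."""
    k, seq, frac = _breaks(rng, n_gam, morgans)
    cnt = _segment_index(seq, frac, mf, n_gam)
    start = rng.integers(0, 2, n_gam, dtype=np.int32)
    return ((start[:, None] + cnt) % 2).astype(np.int8)


def _mosaic_haplotypes(
    rng: np.random.Generator, p: np.ndarray, mf: np.ndarray, lam: np.ndarray
) -> np.ndarray:
    """(n_hap, m) segmental ancestry mosaics; segment states iid Bernoulli(p)."""
    n_hap = p.size
    k, seq, frac = _breaks(rng, n_hap, lam)
    cnt = _segment_index(seq, frac, mf, n_hap)
    states = (rng.random((n_hap, int(k.max(initial=0)) + 1)) < p[:, None]).astype(np.int8)
    return np.take_along_axis(states, cnt, axis=1)


def _founder_switch_rate(p: np.ndarray, generations: float) -> np.ndarray:
    """Expected ancestry junctions per Morgan per haplotype."""
    return 2.0 * p * (1.0 - p) * generations


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def simulate_population(
    model: ClusterModel,
    n: int,
    seed: int | np.random.Generator = 0,
    return_clusters: bool = False,
):
    """Sample hybrid indices for a bimodal population.

    Each individual is assigned cluster A with probability ``model.mix_a``
    and its hybrid index drawn from that cluster's [0, 1]-truncated normal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals, cluster = model.sample(n, rng)
    return (vals, cluster) if return_clusters else vals


def simulate_gamete(
    parent_haplotypes: np.ndarray,
    markers: MarkerMap,
    xo: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one gamete from a phased diploid parent.

    ``parent_haplotypes`` has shape (2, n_markers) with per-marker haploid
    ancestry in {0, 1}.  Per chromosome, the crossover count is Poisson in
    the genetic length, breakpoints are uniform on physical length, the
    starting haplotype is equiprobable and alternates at each breakpoint.
    """
    xo = xo or CrossoverModel()
    haps = np.asarray(parent_haplotypes)
    if haps.shape != (2, markers.n_markers):
        raise ValueError(
            f"parent haplotypes shape {haps.shape} does not match map with "
            f"{markers.n_markers} markers"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    morgans = xo.morgans(markers)
    out = np.empty(markers.n_markers, dtype=np.int8)
    for ci in range(markers.n_chromosomes):
        sl = markers.chrom_slice(ci)
        mf = markers.pos[sl] / markers.length_bp[ci]
        choice = _crossover_choice(rng, 1, mf, float(morgans[ci]))[0]
        out[sl] = np.where(choice == 0, haps[0, sl], haps[1, sl])
    return out


def _f2_genotype_batch(
    rng: np.random.Generator, n: int, markers: MarkerMap, morgans: np.ndarray
) -> np.ndarray:
    """(n, m) F2 genotypes: sum of two independent F1 gametes."""
    geno = np.empty((n, markers.n_markers), dtype=np.int8)
    for ci in range(markers.n_chromosomes):
        sl = markers.chrom_slice(ci)
        mf = markers.pos[sl] / markers.length_bp[ci]
        # an F1 is heterozygous everywhere, so a gamete's ancestry equals the
        # haplotype-choice process itself
        g1 = _crossover_choice(rng, n, mf, float(morgans[ci]))
        g2 = _crossover_choice(rng, n, mf, float(morgans[ci]))
        geno[:, sl] = g1 + g2
    return geno


def simulate_f2_cohort(
    n: int,
    markers: MarkerMap | None = None,
    xo: CrossoverModel | None = None,
    selected_loci: Sequence[tuple[int | tuple[str, int], SelectionParams]] = (),
    seed: int | np.random.Generator = 0,
) -> AncestryMatrix:
    """Simulate n surviving F2 hybrids with optional viability selection.

    Each F2 is the union of two independent F1 gametes.  Survival probability
    is the product over selected loci of the viability fitness (1, 1-h*s,
    1-s) for genotype (CC, BC, BB); cohorts are drawn until ``n`` survivors
    are collected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    markers = markers if markers is not None else default_genome()
    xo = xo or CrossoverModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    morgans = xo.morgans(markers)
    loci: list[tuple[int, SelectionParams]] = []
    for marker, params in selected_loci:
        col = markers.locate(*marker) if isinstance(marker, tuple) else int(marker)
        if not (0 <= col < markers.n_markers):
            raise ValueError(f"selected locus column {col} not on the map")
        loci.append((col, params))
    # mean survival under Mendelian genotype frequencies, for batch sizing
    exp_surv = 1.0
    for _, params in loci:
        w = params.fitnesses()
        exp_surv *= 0.25 * w[0] + 0.5 * w[1] + 0.25 * w[2]
    if exp_surv == 0.0:
        raise ValueError("selection parameters give zero expected survival")
    rows: list[np.ndarray] = []
    collected = 0
    while collected < n:
        batch = max(32, int(np.ceil(1.2 * (n - collected) / max(exp_surv, 0.02))))
        geno = _f2_genotype_batch(rng, batch, markers, morgans)
        if loci:
            w = np.ones(batch)
            for col, params in loci:
                w *= params.fitnesses()[2 - geno[:, col]]  # fitness index (CC,BC,BB)
            keep = rng.random(batch) < w
            geno = geno[keep]
        rows.append(geno)
        collected += geno.shape[0]
    calls = np.concatenate(rows, axis=0)[:n]
    return AncestryMatrix(
        individuals=[f"F2_{i:04d}" for i in range(n)], markers=markers, calls=calls
    )


@dataclass
class MotherEmbryoPanel:
    """Simulated mother/embryo hybrid-index panel.

    ``mother_of_embryo`` maps each embryo to its mother's row; clusters are
    coded 0 (near-pure X. birchmanni) / 1 (admixed).
    """

    mother_index: np.ndarray
    mother_cluster: np.ndarray
    father_index: np.ndarray
    father_cluster: np.ndarray
    embryo_index: np.ndarray
    mother_of_embryo: np.ndarray

    @property
    def n_mothers(self) -> int:
        return self.mother_index.size

    @property
    def n_embryos(self) -> int:
        return self.embryo_index.size

    def pairs(self) -> list[tuple[float, float]]:
        """(mother index, embryo index) per embryo, panel order preserved."""
        return [
            (float(self.mother_index[m]), float(e))
            for m, e in zip(self.mother_of_embryo, self.embryo_index)
        ]

    def differences(self) -> np.ndarray:
        """Signed embryo - mother hybrid-index differences."""
        return self.embryo_index - self.mother_index[self.mother_of_embryo]

    def is_cross_cluster(self) -> np.ndarray:
        """True for embryos whose parents came from different clusters."""
        return (self.mother_cluster[self.mother_of_embryo] != self.father_cluster[self.mother_of_embryo])


def simulate_mother_embryo_panel(
    model: ClusterModel,
    mating: MatingModel,
    n_mothers: int,
    embryos_per_mother: int | Sequence[int],
    markers: MarkerMap | None = None,
    xo: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
    founder_generations: float = DEFAULT_FOUNDER_GENERATIONS,
) -> MotherEmbryoPanel:
    """Simulate wild-caught pregnant mothers and their embryos' ancestries.

    Mothers and fathers are founder mosaics whose target hybrid indices come
    from the cluster model, paired according to the mating model (one father
    per brood; multiple paternity is not modelled).  Each embryo's index is
    the mean of one simulated gamete fraction per parent, so its expectation
    is the midparent index and its spread reflects finite-genome segregation.
    """
    if n_mothers < 1:
        raise ValueError("n_mothers must be >= 1")
    epm = (
        np.full(n_mothers, int(embryos_per_mother), dtype=np.int64)
        if np.isscalar(embryos_per_mother)
        else np.asarray(embryos_per_mother, dtype=np.int64)
    )
    if epm.shape != (n_mothers,) or np.any(epm < 1):
        raise ValueError("embryos_per_mother must be >= 1 for every mother")
    markers = markers if markers is not None else default_genome()
    xo = xo or CrossoverModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    morgans = xo.morgans(markers)

    mother_cluster = (rng.random(n_mothers) >= model.mix_a).astype(np.int8)
    father_cluster = mating.father_clusters(mother_cluster, model.mix_a, rng)

    def _targets(cluster):
        mean = np.where(cluster == 0, model.mean_a, model.mean_b)
        sd = np.where(cluster == 0, model.sd_a, model.sd_b)
        vals = rng.normal(mean, sd)
        bad = (vals < 0) | (vals > 1)
        while bad.any():
            vals[bad] = rng.normal(mean[bad], sd[bad])
            bad = (vals < 0) | (vals > 1)
        return vals

    p_m, p_f = _targets(mother_cluster), _targets(father_cluster)
    mother_of_embryo = np.repeat(np.arange(n_mothers), epm)
    n_embryos = int(epm.sum())

    m_total = markers.n_markers
    mother_sum = np.zeros(n_mothers)
    father_sum = np.zeros(n_mothers)
    gam_m_sum = np.zeros(n_embryos)
    gam_f_sum = np.zeros(n_embryos)
    # per-haplotype p for the stacked (mother, father) founder haplotypes
    p_hap_m = np.repeat(p_m, 2)
    p_hap_f = np.repeat(p_f, 2)
    for ci in range(markers.n_chromosomes):
        sl = markers.chrom_slice(ci)
        mf = markers.pos[sl] / markers.length_bp[ci]
        lam_m = _founder_switch_rate(p_hap_m, founder_generations) * morgans[ci]
        lam_f = _founder_switch_rate(p_hap_f, founder_generations) * morgans[ci]
        mh = _mosaic_haplotypes(rng, p_hap_m, mf, lam_m)  # (2*n_mothers, m)
        fh = _mosaic_haplotypes(rng, p_hap_f, mf, lam_f)
        mh0, mh1 = mh[0::2], mh[1::2]
        fh0, fh1 = fh[0::2], fh[1::2]
        mother_sum += (mh0 + mh1).sum(axis=1) / 2.0
        father_sum += (fh0 + fh1).sum(axis=1) / 2.0
        cm = _crossover_choice(rng, n_embryos, mf, float(morgans[ci]))
        cf = _crossover_choice(rng, n_embryos, mf, float(morgans[ci]))
        gm = np.where(cm == 0, mh0[mother_of_embryo], mh1[mother_of_embryo])
        gf = np.where(cf == 0, fh0[mother_of_embryo], fh1[mother_of_embryo])
        gam_m_sum += gm.sum(axis=1)
        gam_f_sum += gf.sum(axis=1)

    return MotherEmbryoPanel(
        mother_index=mother_sum / m_total,
        mother_cluster=mother_cluster,
        father_index=father_sum / m_total,
        father_cluster=father_cluster,
        embryo_index=(gam_m_sum + gam_f_sum) / (2.0 * m_total),
        mother_of_embryo=mother_of_embryo,
    )


def add_call_noise(
    matrix: AncestryMatrix,
    error_rate: float,
    missing_rate: float,
    seed: int | np.random.Generator = 0,
) -> AncestryMatrix:
    """Apply independent per-call dropout and genotyping error.

    Each non-missing call is set to missing with ``missing_rate``, otherwise
    flipped to a uniformly chosen different state with ``error_rate``.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = matrix.calls.copy()
    present = calls != MISSING
    drop = present & (rng.random(calls.shape) < missing_rate)
    calls[drop] = MISSING
    present &= ~drop
    flip = present & (rng.random(calls.shape) < error_rate)
    # uniformly one of the two other states
    offset = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
    calls[flip] = (calls[flip] + offset[flip]) % 3
    return AncestryMatrix(
        individuals=list(matrix.individuals), markers=matrix.markers, calls=calls
    )


def write_panel(panel: MotherEmbryoPanel, path) -> None:
    """Tab-separated panel: mother_id, mother_index, embryo_id, embryo_index."""
    with open(path, "w") as fh:
        fh.write("mother_id\tmother_index\tembryo_id\tembryo_index\n")
        for j, (mi, e) in enumerate(zip(panel.mother_of_embryo, panel.embryo_index)):
            fh.write(
                f"M{mi:04d}\t{panel.mother_index[mi]:.6f}\tE{j:04d}\t{e:.6f}\n"
            )
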