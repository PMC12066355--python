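import numpy as np
import pytest

from hybridbarriers.ancestry_core import MISSING, hybrid_index
from hybridbarriers.selection_abc import SelectionParams
from hybridbarriers.synthetic_data import (
    ClusterModel,
    CrossoverModel,
    MatingModel,
    add_call_noise,
    default_genome,
    simulate_f2_cohort,
    simulate_gamete,
    simulate_mother_embryo_panel,
    simulate_population,
)


class TestClusterModel:
    def test_printed_cluster_means_recovered(self, printed_clusters):
        vals, cluster = simulate_population(printed_clusters, 10_000, seed=0, return_clusters=True)
        a = vals[cluster == 0]
        se = printed_clusters.sd_a / np.sqrt(a.size)
        assert abs(a.mean() - 0.019) < 3 * se
        b = vals[cluster == 1]
        assert abs(b.mean() - 0.757) < 3 * (printed_clusters.sd_b / np.sqrt(b.size))
        # mixing proportion ~62%
        assert abs((cluster == 0).mean() - 0.62) < 0.02

    def test_pure_cluster_a(self):
        model = ClusterModel(mix_a=1.0)
        vals, cluster = simulate_population(model, 500, seed=1, return_clusters=True)
        assert (cluster == 0).all()
        assert vals.max() < 0.1

    def test_zero_sd_gives_point_masses(self):
        model = ClusterModel(sd_a=0.0, sd_b=0.0)
        vals = simulate_population(model, 200, seed=2)
        assert set(np.round(vals, 9)) == {0.019, 0.757}

    def test_samples_truncated_to_unit_interval(self):
        model = ClusterModel(mean_a=0.01, sd_a=0.2, mean_b=0.99, sd_b=0.2)
        vals = simulate_population(model, 2000, seed=3)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ClusterModel(mean_a=1.5)
        with pytest.raises(ValueError):
            ClusterModel(sd_a=-0.1)

    def test_seed_reproducibility(self, printed_clusters):
        assert np.array_equal(
            simulate_population(printed_clusters, 100, seed=4),
            simulate_population(printed_clusters, 100, seed=4),
        )


class TestSimulateGamete:
    def test_zero_genetic_length_is_unbroken(self, small_genome):
        xo = CrossoverModel(morgans_override=(0.0,) * 4)
        haps = np.vstack(
            [np.ones(small_genome.n_markers), np.zeros(small_genome.n_markers)]
        ).astype(np.int8)
        gam = simulate_gamete(haps, small_genome, xo, seed=0)
        for ci in range(4):
            sl = small_genome.chrom_slice(ci)
            assert np.unique(gam[sl]).size == 1  # one parental haplotype per chromosome

    def test_f1_gamete_is_unbiased(self, small_genome):
        rng = np.random.default_rng(5)
        haps = np.vstack(
            [np.ones(small_genome.n_markers), np.zeros(small_genome.n_markers)]
        ).astype(np.int8)
        fracs = [simulate_gamete(haps, small_genome, seed=rng).mean() for _ in range(400)]
        # mean over 400 x 4 chromosomes: SE ~ 0.29/sqrt(400*4)
        assert abs(np.mean(fracs) - 0.5) < 3 * 0.29 / np.sqrt(1600)

    def test_poisson_breakpoint_mean(self, small_genome):
        """Observed haplotype switches per chromosome match the 1-Morgan
        Poisson rate after accounting for marker discretization."""
        rng = np.random.default_rng(6)
        haps = np.vstack(
            [np.ones(small_genome.n_markers), np.zeros(small_genome.n_markers)]
        ).astype(np.int8)
        switches = []
        sl = small_genome.chrom_slice(0)
        for _ in range(2000):
            gam = simulate_gamete(haps, small_genome, seed=rng)
            switches.append(int(np.abs(np.diff(gam[sl])).sum()))
        # a marker gap of width w (Morgans) shows a switch iff it received an
        # odd number of crossovers: P = (1 - exp(-2w))/2; summing over gaps
        # gives the expected observable switch count (< 1.0 because pairs
        # within one gap cancel and tail crossovers are invisible)
        mf = small_genome.pos[sl] / small_genome.length_bp[0]
        expected = ((1 - np.exp(-2 * np.diff(mf))) / 2).sum()
        assert abs(np.mean(switches) - expected) < 3 * np.sqrt(expected / 2000)

    def test_shape_mismatch_errors(self, small_genome):
        with pytest.raises(ValueError):
            simulate_gamete(np.zeros((2, 7)), small_genome)


class TestF2Cohort:
    def test_mendelian_frequencies_without_selection(self, small_genome):
        am = simulate_f2_cohort(2000, small_genome, seed=7)
        freqs = [(am.calls == g).mean() for g in (2, 1, 0)]
        assert freqs[0] == pytest.approx(0.25, abs=0.02)
        assert freqs[1] == pytest.approx(0.50, abs=0.02)
        assert freqs[2] == pytest.approx(0.25, abs=0.02)
        assert am.calls.mean() / 2 == pytest.approx(0.5, abs=0.01)

    def test_grand_mean_over_repeated_cohorts(self, small_genome):
        rng = np.random.default_rng(8)
        means = [
            simulate_f2_cohort(163, small_genome, seed=rng).calls.mean() / 2
            for _ in range(200)
        ]
        assert 0.49 < np.mean(means) < 0.51

    def test_lethal_recessive_removes_bb(self, small_genome):
        locus = 20
        am = simulate_f2_cohort(
            500, small_genome, selected_loci=[(locus, SelectionParams(1.0, 0.0))], seed=9
        )
        col = am.calls[:, locus]
        assert (col == 0).sum() == 0
        # surviving frequencies renormalise to (1/3 CC, 2/3 BC)
        assert (col == 2).mean() == pytest.approx(1 / 3, abs=0.06)
        assert (col == 1).mean() == pytest.approx(2 / 3, abs=0.06)

    def test_admixture_ld_structure(self, small_genome):
        """Ancestry correlation decays along a chromosome and vanishes between
        chromosomes."""
        am = simulate_f2_cohort(10_000, small_genome, seed=10)
        g = am.calls.astype(float)
        sl = small_genome.chrom_slice(0)
        r_near = np.corrcoef(g[:, sl.start], g[:, sl.start + 1])[0, 1] ** 2
        r_far = np.corrcoef(g[:, sl.start], g[:, sl.stop - 1])[0, 1] ** 2
        r_cross = np.corrcoef(g[:, sl.start], g[:, small_genome.chrom_slice(1).start])[0, 1] ** 2
        assert r_near > r_far
        assert r_cross < 0.01

    def test_selection_params_validated(self, small_genome):
        with pytest.raises(ValueError):
            simulate_f2_cohort(
                10, small_genome, selected_loci=[(0, SelectionParams(1.5, 0.0))], seed=0
            )

    def test_reproducible(self, small_genome):
        a = simulate_f2_cohort(50, small_genome, seed=11)
        b = simulate_f2_cohort(50, small_genome, seed=11)
        assert np.array_equal(a.calls, b.calls)


class TestMotherEmbryoPanel:
    def test_assortative_pairs_align_with_mother(self, small_genome, printed_clusters):
        panel = simulate_mother_embryo_panel(
            printed_clusters, MatingModel("assortative", 1.0), 200, 2, small_genome, seed=12
        )
        # no pair approaches the cross-cluster classification threshold
        assert np.abs(panel.differences()).max() < (0.757 - 0.019) / 4

    def test_cross_cluster_midparent_expectation(self, small_genome, printed_clusters):
        panel = simulate_mother_embryo_panel(
            printed_clusters, MatingModel("cross_cluster"), 3000, 1, small_genome, seed=13
        )
        d = np.abs(panel.differences())
        # expectation (0.757 - 0.019)/2 = 0.369
        assert d.mean() == pytest.approx(0.369, abs=0.01)
        assert abs(d.mean() - 0.369) < 2 * d.std()

    def test_embryo_expectation_is_midparent(self, small_genome, printed_clusters):
        panel = simulate_mother_embryo_panel(
            printed_clusters, MatingModel("random"), 2000, 1, small_genome, seed=14
        )
        mid = (panel.mother_index + panel.father_index) / 2
        resid = panel.embryo_index - mid[panel.mother_of_embryo]
        assert abs(resid.mean()) < 0.005

    def test_zero_embryos_errors(self, small_genome, printed_clusters):
        with pytest.raises(ValueError):
            simulate_mother_embryo_panel(
                printed_clusters, MatingModel("random"), 5, 0, small_genome, seed=0
            )

    def test_invalid_mating_model_errors(self):
        with pytest.raises(ValueError):
            MatingModel("disassortative")
        with pytest.raises(ValueError):
            MatingModel("assortative", 1.5)

    def test_reproducible(self, small_genome, printed_clusters):
        a = simulate_mother_embryo_panel(
            printed_clusters, MatingModel("random"), 20, 2, small_genome, seed=15
        )
        b = simulate_mother_embryo_panel(
            printed_clusters, MatingModel("random"), 20, 2, small_genome, seed=15
        )
        assert np.array_equal(a.embryo_index, b.embryo_index)


class TestAddCallNoise:
    def test_zero_rates_identity(self, tiny_matrix):
        out = add_call_noise(tiny_matrix, 0.0, 0.0, seed=0)
        assert np.array_equal(out.calls, tiny_matrix.calls)

    def test_full_missingness(self, tiny_matrix):
        out = add_call_noise(tiny_matrix, 0.0, 1.0, seed=0)
        assert (out.calls == MISSING).all()

    def test_error_rate_binomial(self, small_genome):
        am = simulate_f2_cohort(63, small_genome, seed=16)  # ~10,080 calls
        n_calls = am.calls.size
        out = add_call_noise(am, 0.01, 0.0, seed=17)
        flips = (out.calls != am.calls).sum()
        expected = 0.01 * n_calls
        assert abs(flips - expected) < 3 * np.sqrt(expected)
        assert not (out.calls == MISSING).any()

    def test_rates_validated(self, tiny_matrix):
        with pytest.raises(ValueError):
            add_call_noise(tiny_matrix, 1.5, 0.0)


class TestDefaultGenome:
    def test_dimensions(self):
        mm = default_genome()
        assert mm.n_chromosomes == 24
        assert mm.n_markers == 24 * 500
        assert (mm.length_bp == 25_000_000).all()
        assert (mm.length_morgans == 1.0).all()

    def test_hybrid_index_of_f1_genotypes(self, small_genome):
        calls = np.ones(small_genome.n_markers, dtype=np.int8)
        assert hybrid_index(calls).value == 0.5
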