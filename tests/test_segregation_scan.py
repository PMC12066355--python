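import numpy as np
import pytest

from hybridbarriers.ancestry_core import MISSING, AncestryMatrix, MarkerMap
from hybridbarriers.segregation_scan import (
    find_distorted_regions,
    ld_interval,
    null_envelope,
    r_squared,
    scan_mean_ancestry,
    thin_markers,
)
from hybridbarriers.selection_abc import SelectionParams
from hybridbarriers.synthetic_data import simulate_f2_cohort


def _matrix_from_calls(calls, spacing=10_000):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    mm = MarkerMap(
        chroms=("chr1",),
        chrom_index=np.zeros(m, dtype=int),
        pos=spacing * np.arange(m) + 1,
        length_bp=np.array([spacing * m]),
        length_morgans=np.array([1.0]),
    )
    return AncestryMatrix(
        individuals=[f"i{k}" for k in range(calls.shape[0])], markers=mm, calls=calls
    )


class TestScanMeanAncestry:
    def test_all_heterozygous(self):
        am = _matrix_from_calls(np.ones((5, 4)))
        assert scan_mean_ancestry(am) == pytest.approx([0.5] * 4)

    def test_symmetric_calls(self):
        am = _matrix_from_calls([[0], [1], [2]])
        assert scan_mean_ancestry(am)[0] == pytest.approx(0.5)

    def test_missing_excluded(self):
        am = _matrix_from_calls([[2], [2], [1], [MISSING]])
        assert scan_mean_ancestry(am)[0] == pytest.approx(5 / 6)

    def test_all_missing_marker_is_nan(self):
        am = _matrix_from_calls([[MISSING, 1], [MISSING, 1]])
        scan = scan_mean_ancestry(am)
        assert np.isnan(scan[0]) and scan[1] == 0.5


class TestNullEnvelope:
    def test_envelope_roughly_symmetric(self, small_genome):
        low, high = null_envelope(small_genome, 163, n_reps=400, seed=0)
        assert abs((0.5 - low[0]) - (high[0] - 0.5)) < 0.02
        assert low[0] < 0.5 < high[0]

    def test_tightens_with_sample_size(self, small_genome):
        low_s, high_s = null_envelope(small_genome, 100, n_reps=200, seed=1)
        low_l, high_l = null_envelope(small_genome, 2000, n_reps=200, seed=2)
        assert (high_l[0] - low_l[0]) < (high_s[0] - low_s[0])

    def test_alpha_one_collapses_to_median(self, small_genome):
        low, high = null_envelope(small_genome, 163, n_reps=200, alpha=1.0, seed=3)
        # degenerate quantiles: median of minima / maxima straddle 0.5 narrowly
        assert 0.35 < low[0] <= high[0] < 0.65

    def test_nreps_validated(self, small_genome):
        with pytest.raises(ValueError):
            null_envelope(small_genome, 163, n_reps=50)


class TestFindDistortedRegions:
    def test_no_flags_at_half(self, small_genome):
        m = small_genome.n_markers
        scan = np.full(m, 0.5)
        env = (np.full(m, 0.4), np.full(m, 0.6))
        res = find_distorted_regions(scan, env, small_genome)
        assert not res.flagged.any()
        assert res.intervals == []

    def test_single_marker_interval_and_peak(self, small_genome):
        m = small_genome.n_markers
        scan = np.full(m, 0.5)
        scan[10] = 0.9
        env = (np.full(m, 0.38), np.full(m, 0.62))
        res = find_distorted_regions(scan, env, small_genome)
        assert res.flagged.sum() == 1
        assert len(res.intervals) == 1
        chrom, start, end, peak = res.intervals[0]
        assert peak == 10
        assert end - start == 1  # single marker, half-open

    def test_gap_tolerance_merges_runs(self, small_genome):
        m = small_genome.n_markers
        scan = np.full(m, 0.5)
        scan[[5, 7, 8]] = 0.95  # marker 6 unflagged but within gap tolerance
        env = (np.full(m, 0.38), np.full(m, 0.62))
        res = find_distorted_regions(scan, env, small_genome)
        assert len(res.intervals) == 1

    def test_envelope_mismatch_errors(self, small_genome):
        scan = np.full(small_genome.n_markers, 0.5)
        env = (np.full(3, 0.4), np.full(3, 0.6))
        with pytest.raises(ValueError):
            find_distorted_regions(scan, env, small_genome)


class TestThinMarkers:
    def test_every_fifth_marker(self):
        am = _matrix_from_calls(np.ones((2, 20)), spacing=10_000)
        thinned = thin_markers(am, 50_000)
        assert thinned.markers.n_markers == 4
        assert np.array_equal(thinned.markers.pos, am.markers.pos[::5])

    def test_spacing_larger_than_chromosome(self):
        am = _matrix_from_calls(np.ones((2, 20)), spacing=10_000)
        thinned = thin_markers(am, 10**9)
        assert thinned.markers.n_markers == 1

    def test_unit_spacing_is_identity(self):
        am = _matrix_from_calls(np.ones((2, 20)), spacing=10_000)
        thinned = thin_markers(am, 1)
        assert np.array_equal(thinned.calls, am.calls)


class TestRSquared:
    def test_identical_vectors(self):
        assert r_squared([0, 1, 2, 1, 0], [0, 1, 2, 1, 0]) == pytest.approx(1.0)

    def test_exact_cancellation(self):
        assert r_squared([0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        expected = (np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))) ** 2
        assert r_squared(x, y) == pytest.approx(expected)

    def test_pairwise_complete_only(self):
        x = [0, 1, 2, MISSING, 2]
        y = [0, 1, 2, 2, MISSING]
        assert r_squared(x, y) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [0, 1, 2])

    def test_independent_markers_near_zero(self, small_genome):
        am = simulate_f2_cohort(10_000, small_genome, seed=5)
        a = small_genome.chrom_slice(0).start
        b = small_genome.chrom_slice(2).start
        assert r_squared(am.calls[:, a], am.calls[:, b]) < 0.01


@pytest.fixture(scope="module")
def cohort(small_genome):
    return simulate_f2_cohort(400, small_genome, seed=6)


class TestLdInterval:
    def test_interval_contains_peak(self, cohort, small_genome):
        peak = small_genome.chrom_slice(1).start + 20
        iv = ld_interval(cohort, peak, spacing_bp=50_000, r2_threshold=0.8)
        pos = small_genome.pos[peak]
        assert iv.start <= pos - 1 < iv.end
        assert iv.chrom == "chr2"

    def test_zero_threshold_spans_chromosome(self, cohort, small_genome):
        peak = small_genome.chrom_slice(1).start + 20
        iv = ld_interval(cohort, peak, spacing_bp=50_000, r2_threshold=0.0)
        sl = small_genome.chrom_slice(1)
        assert iv.start == int(small_genome.pos[sl.start] - 1)

    def test_width_shrinks_with_threshold(self, cohort, small_genome):
        peak = small_genome.chrom_slice(1).start + 20
        widths = []
        for thr in (0.2, 0.5, 0.8, 0.95):
            iv = ld_interval(cohort, peak, spacing_bp=50_000, r2_threshold=thr)
            widths.append(iv.end - iv.start)
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    def test_strict_threshold_with_noise_collapses(self, small_genome):
        from hybridbarriers.synthetic_data import add_call_noise

        am = simulate_f2_cohort(400, small_genome, seed=7)
        noisy = add_call_noise(am, error_rate=0.02, missing_rate=0.0, seed=8)
        peak = small_genome.chrom_slice(0).start + 20
        iv = ld_interval(noisy, peak, spacing_bp=50_000, r2_threshold=1.0)
        assert iv.end - iv.start <= 100_000  # at most the peak's own window


class TestPowerAgainstSelection:
    def test_lethal_recessive_locus_is_flagged(self, small_genome):
        """End-to-end power check on a small genome: a lethal-recessive locus
        produces a flagged interval overlapping the locus."""
        locus = small_genome.chrom_slice(2).start + 20
        env = null_envelope(small_genome, 163, n_reps=300, seed=9)
        am = simulate_f2_cohort(
            163, small_genome, selected_loci=[(locus, SelectionParams(1.0, 0.0))], seed=10
        )
        res = find_distorted_regions(am, env)
        assert res.flagged[locus]

    def test_null_cohort_rarely_flagged(self, small_genome):
        env = null_envelope(small_genome, 163, n_reps=500, seed=11)
        hits = 0
        rng = np.random.default_rng(12)
        for _ in range(40):
            am = simulate_f2_cohort(163, small_genome, seed=rng)
            if find_distorted_regions(am, env).flagged.any():
                hits += 1
        assert hits <= 8  # ~5% expected; allow generous Monte-Carlo slack
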