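"""Genome-wide segregation-distortion scan for F2 cohorts.

In an unselected F2 intercross every marker has expected X. cortezi ancestry
0.5; viability selection shows up as markers whose mean ancestry among
surviving adults deviates from 0.5.  Because admixture linkage disequilibrium
in F2s spans many megabases, significance is assessed genome-wide: unselected
cohorts of the same size are simulated, the per-replicate extrema of
per-marker mean ancestry recorded, and their quantiles form a family-wise
(1 - alpha) envelope.  Distorted intervals are then delimited by the decay of
ancestry correlation (R^2) around the peak marker after thinning markers to
one per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry_core import MISSING, AncestryMatrix, MarkerMap
from .synthetic_data import CrossoverModel, _f2_genotype_batch

__all__ = [
    "ScanResult",
    "LDInterval",
    "scan_mean_ancestry",
    "null_envelope",
    "find_distorted_regions",
    "thin_markers",
    "r_squared",
    "ld_interval",
]


@dataclass(frozen=True)
class ScanResult:
    """Per-marker mean ancestry with the null envelope and flagged intervals."""

    markers: MarkerMap
    mean_ancestry: np.ndarray  # NaN where no calls
    low: np.ndarray
    high: np.ndarray
    flagged: np.ndarray  # bool per marker
    intervals: list[tuple[str, int, int, int]]  # (chrom, start, end, peak column)

    def bed_intervals(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, _ in self.intervals]


@dataclass(frozen=True)
class LDInterval:
    """Contiguous region around a peak marker with R^2 above a threshold."""

    chrom: str
    peak_column: int
    start: int  # 0-based half-open bp
    end: int
    r2: dict[int, float]  # per retained thinned column, R^2 to the peak


def scan_mean_ancestry(matrix: AncestryMatrix) -> np.ndarray:
    """Per-marker mean X. cortezi ancestry (call value / 2) over non-missing calls.

    Markers where every call is missing get NaN (excluded from envelope
    comparison downstream).
    """
    if matrix.n_individuals < 1:
        raise ValueError("need at least one individual")
    calls = matrix.calls
    ok = calls != MISSING
    n_ok = ok.sum(axis=0)
    sums = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_ok > 0, sums / (2.0 * n_ok), np.nan)


def null_envelope(
    markers: MarkerMap,
    n_individuals: int,
    n_reps: int = 1000,
    alpha: float = 0.05,
    xo: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Family-wise (1 - alpha) envelope for mean ancestry in unselected F2s.

    Simulates ``n_reps`` unselected cohorts of ``n_individuals``; per
    replicate records the genome-wide minimum and maximum of per-marker mean
    ancestry; returns ``low`` = alpha/2 quantile of minima and ``high`` =
    1 - alpha/2 quantile of maxima, broadcast to every marker (genome-wide
    control of the family-wise error rate).
    """
    if n_reps < 200:
        raise ValueError("n_reps must be >= 200")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    xo = xo or CrossoverModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    morgans = xo.morgans(markers)
    minima = np.empty(n_reps)
    maxima = np.empty(n_reps)
    for r in range(n_reps):
        geno = _f2_genotype_batch(rng, n_individuals, markers, morgans)
        means = geno.mean(axis=0) / 2.0
        minima[r] = means.min()
        maxima[r] = means.max()
    low = float(np.quantile(minima, alpha / 2.0))
    high = float(np.quantile(maxima, 1.0 - alpha / 2.0))
    m = markers.n_markers
    return np.full(m, low), np.full(m, high)


def find_distorted_regions(
    matrix_or_scan: AncestryMatrix | np.ndarray,
    envelope: tuple[np.ndarray, np.ndarray],
    markers: MarkerMap | None = None,
    gap_tolerance: int = 1,
) -> ScanResult:
    """Flag markers outside the envelope and merge them into intervals.

    Runs of flagged markers separated by at most ``gap_tolerance`` unflagged
    markers are merged; each interval reports its most extreme marker (largest
    |mean - 0.5|) as the peak.  Intervals are BED-style 0-based half-open.
    """
    if isinstance(matrix_or_scan, AncestryMatrix):
        markers = matrix_or_scan.markers
        scan = scan_mean_ancestry(matrix_or_scan)
    else:
        scan = np.asarray(matrix_or_scan, dtype=float)
        if markers is None:
            raise ValueError("markers map required when passing a raw scan vector")
    low, high = envelope
    if scan.shape != low.shape or scan.shape != high.shape or scan.size != markers.n_markers:
        raise ValueError("scan and envelope must align with the marker map")
    with np.errstate(invalid="ignore"):
        flagged = (scan < low) | (scan > high)
    flagged &= ~np.isnan(scan)

    intervals: list[tuple[str, int, int, int]] = []
    for ci in range(markers.n_chromosomes):
        sl = markers.chrom_slice(ci)
        cols = np.flatnonzero(flagged[sl]) + sl.start
        if cols.size == 0:
            continue
        runs: list[list[int]] = [[int(cols[0])]]
        for col in cols[1:]:
            if col - runs[-1][-1] <= gap_tolerance + 1:
                runs[-1].append(int(col))
            else:
                runs.append([int(col)])
        for run in runs:
            dev = np.abs(scan[run] - 0.5)
            peak = run[int(np.argmax(dev))]
            start = int(markers.pos[run[0]] - 1)
            end = int(markers.pos[run[-1]])
            intervals.append((markers.chroms[ci], start, end, peak))
    return ScanResult(
        markers=markers,
        mean_ancestry=scan,
        low=low,
        high=high,
        flagged=flagged,
        intervals=intervals,
    )


def thin_markers(matrix: AncestryMatrix, spacing_bp: int = 50_000) -> AncestryMatrix:
    """Retain the first marker in each non-overlapping window per chromosome."""
    if spacing_bp <= 0:
        raise ValueError("spacing must be > 0")
    keep = _thin_columns(matrix.markers, spacing_bp)
    mm = matrix.markers
    thinned = MarkerMap(
        chroms=mm.chroms,
        chrom_index=mm.chrom_index[keep],
        pos=mm.pos[keep],
        length_bp=mm.length_bp,
        length_morgans=mm.length_morgans,
    )
    return AncestryMatrix(
        individuals=list(matrix.individuals),
        markers=thinned,
        calls=matrix.calls[:, keep],
    )


def _thin_columns(markers: MarkerMap, spacing_bp: int) -> np.ndarray:
    """Column indices of the first marker per non-overlapping window."""
    window = (markers.pos - 1) // spacing_bp
    key = markers.chrom_index * (int(window.max(initial=0)) + 1) + window
    first = np.ones(markers.n_markers, dtype=bool)
    first[1:] = key[1:] != key[:-1]
    return np.flatnonzero(first)


def r_squared(x, y) -> float:
    """Squared Pearson correlation of 0/1/2 ancestry codes.

    Computed over pairwise-complete individuals (both calls non-missing);
    requires at least two complete pairs and nonzero variance in both
    vectors.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = (xv != MISSING) & (yv != MISSING)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete individuals")
    xv, yv = xv[ok], yv[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance; R^2 undefined")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_interval(
    matrix: AncestryMatrix,
    peak: int | tuple[str, int],
    spacing_bp: int = 50_000,
    r2_threshold: float = 0.8,
) -> LDInterval:
    """Delimit the distorted interval by R^2 decay around the peak marker.

    Markers are thinned to one per ``spacing_bp`` window; walking outward
    from the peak in each direction, the interval ends just before the first
    thinned marker whose R^2 to the peak falls below ``r2_threshold`` (no
    re-entry).  Returned as 0-based half-open bp on the peak's chromosome.
    """
    mm = matrix.markers
    peak_col = mm.locate(*peak) if isinstance(peak, tuple) else int(peak)
    if not (0 <= peak_col < mm.n_markers):
        raise ValueError("peak marker not on the map")
    ci = int(mm.chrom_index[peak_col])
    chrom = mm.chroms[ci]
    keep = _thin_columns(mm, spacing_bp)
    keep = keep[mm.chrom_index[keep] == ci]
    # ensure the peak itself is part of the walk
    if peak_col not in keep:
        keep = np.sort(np.append(keep, peak_col))
    pk = int(np.searchsorted(keep, peak_col))
    peak_calls = matrix.calls[:, peak_col]
    if np.std(peak_calls[peak_calls != MISSING]) == 0.0:
        raise ValueError("peak marker has zero variance")

    r2_map: dict[int, float] = {peak_col: 1.0}
    lo_i = hi_i = pk
    for step, limit in ((-1, -1), (1, keep.size)):
        i = pk + step
        while i != limit:
            col = int(keep[i])
            try:
                r2 = r_squared(peak_calls, matrix.calls[:, col])
            except ValueError:
                break  # zero variance / no overlap terminates the walk
            if r2 < r2_threshold:
                break
            r2_map[col] = r2
            if step < 0:
                lo_i = i
            else:
                hi_i = i
            i += step
    start = int(mm.pos[keep[lo_i]] - 1)
    end = int(mm.pos[keep[hi_i]])
    return LDInterval(chrom=chrom, peak_column=peak_col, start=start, end=end, r2=r2_map)
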