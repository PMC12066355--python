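"""Data model and I/O for ancestry calls, marker maps and hybrid indices.

Ancestry at every ancestry-informative site is coded as the number of
X. cortezi-derived alleles an individual carries:

* ``0`` — homozygous X. birchmanni ("BB")
* ``1`` — heterozygous ("BC")
* ``2`` — homozygous X. cortezi ("CC")
* :data:`MISSING` (``-1``) — no confident call

This coding makes the hybrid index (proportion of the genome derived from
X. cortezi) a linear statistic of the calls.  Missingness is a first-class
state and is never imputed.

File formats
------------
Ancestry matrix
    Tab-separated with header ``chrom  pos  <ind1> <ind2> ...``; positions are
    1-based; values in ``{0, 1, 2, NA}``.
Posterior file
    Tab-separated ``chrom  pos  individual  p_BB  p_BC  p_CC`` (the column
    order of the three posterior probabilities is fixed and documented in the
    header).
Marker map file
    Tab-separated ``chrom  length_bp  length_morgans``, one row per
    chromosome.
Interval export
    BED3: ``chrom  start  end`` with 0-based half-open coordinates (marker
    positions in matrix files remain 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MarkerMap",
    "AncestryMatrix",
    "HybridIndex",
    "GenotypeCounts",
    "threshold_posteriors",
    "threshold_posterior_matrix",
    "hybrid_index",
    "hybrid_indices",
    "genotype_counts_at",
    "pick_representative_site",
    "read_ancestry_matrix",
    "write_ancestry_matrix",
    "read_marker_map",
    "write_marker_map",
    "read_posteriors",
    "write_bed",
]

#: Sentinel for a site with no confident ancestry call.
MISSING: int = -1

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


@dataclass(frozen=True)
class MarkerMap:
    """Genomic coordinates of ancestry-informative markers.

    Markers are stored sorted by chromosome (in ``chroms`` order) and by
    1-based physical position within each chromosome.

    Parameters
    ----------
    chroms
        Ordered unique chromosome identifiers.
    chrom_index
        Per-marker index into ``chroms``.
    pos
        Per-marker 1-based physical position (bp).
    length_bp
        Per-chromosome physical length in bp.
    length_morgans
        Per-chromosome genetic length in Morgans.
    """

    chroms: tuple[str, ...]
    chrom_index: np.ndarray
    pos: np.ndarray
    length_bp: np.ndarray
    length_morgans: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_index", np.asarray(self.chrom_index, dtype=np.int64))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "length_bp", np.asarray(self.length_bp, dtype=np.int64))
        object.__setattr__(
            self, "length_morgans", np.asarray(self.length_morgans, dtype=np.float64)
        )
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("duplicate chromosome identifiers")
        n_chrom = len(self.chroms)
        if self.length_bp.shape != (n_chrom,) or self.length_morgans.shape != (n_chrom,):
            raise ValueError("per-chromosome length arrays must match number of chromosomes")
        if np.any(self.length_morgans < 0):
            raise ValueError("genetic lengths must be >= 0")
        if np.any(self.length_bp < 1):
            raise ValueError("physical lengths must be >= 1 bp")
        if self.chrom_index.shape != self.pos.shape:
            raise ValueError("chrom_index and pos must align")
        if self.pos.size:
            if self.chrom_index.min() < 0 or self.chrom_index.max() >= n_chrom:
                raise ValueError("chrom_index out of range")
            if np.any(np.diff(self.chrom_index) < 0):
                raise ValueError("markers must be grouped by chromosome in chroms order")
            if np.any(self.pos < 1) or np.any(self.pos > self.length_bp[self.chrom_index]):
                raise ValueError("marker positions must lie in [1, chromosome length]")
            same = np.diff(self.chrom_index) == 0
            if np.any(np.diff(self.pos)[same] <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return int(self.pos.size)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chroms)

    def chrom_slice(self, chrom: str | int) -> slice:
        """Contiguous marker slice for one chromosome."""
        ci = chrom if isinstance(chrom, (int, np.integer)) else self.chroms.index(chrom)
        lo, hi = np.searchsorted(self.chrom_index, [ci, ci + 1])
        return slice(int(lo), int(hi))

    def marker_ids(self) -> list[tuple[str, int]]:
        """Marker identifiers as (chrom, 1-based pos) tuples."""
        return [(self.chroms[c], int(p)) for c, p in zip(self.chrom_index, self.pos)]

    def locate(self, chrom: str, pos: int) -> int:
        """Column index of the marker at (chrom, 1-based pos)."""
        sl = self.chrom_slice(chrom)
        i = int(np.searchsorted(self.pos[sl], pos)) + sl.start
        if i >= sl.stop or self.pos[i] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return i

    def markers_in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Column indices of markers in a BED-style 0-based half-open interval."""
        sl = self.chrom_slice(chrom)
        p = self.pos[sl]
        # marker at 1-based pos occupies 0-based [pos-1, pos)
        lo = int(np.searchsorted(p, start + 1)) + sl.start
        hi = int(np.searchsorted(p, end, side="right")) + sl.start
        return np.arange(lo, hi)


@dataclass(frozen=True)
class HybridIndex:
    """Proportion of the genome derived from X. cortezi.

    ``value`` lies in [0, 1]; ``n_calls`` records how many non-missing calls
    the estimate is based on.
    """

    value: float
    n_calls: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"hybrid index {self.value} outside [0, 1]")
        if self.n_calls < 1:
            raise ValueError("hybrid index undefined with zero non-missing calls")


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of ancestry genotypes at one focal locus."""

    n_CC: int
    n_BC: int
    n_BB: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_CC, self.n_BC, self.n_BB, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of genotyped (non-missing) individuals."""
        return self.n_CC + self.n_BC + self.n_BB

    def as_array(self) -> np.ndarray:
        """Counts ordered (CC, BC, BB)."""
        return np.array([self.n_CC, self.n_BC, self.n_BB], dtype=np.int64)


@dataclass
class AncestryMatrix:
    """Hard ancestry calls for a set of individuals over a marker map.

    ``calls`` is an ``(n_individuals, n_markers)`` int8 array with values in
    ``{0, 1, 2, MISSING}``.
    """

    individuals: list[str]
    markers: MarkerMap
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.individuals), self.markers.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {self.markers.n_markers} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid ancestry call values: {np.unique(self.calls[bad])}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individuals.index(individual)]


# ---------------------------------------------------------------------------
# Posterior thresholding
# ---------------------------------------------------------------------------

def _validate_triple(post: Sequence[float], tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(post, dtype=np.float64)
    if p.shape != (3,):
        raise ValueError("posterior triple must have exactly three entries (p_BB, p_BC, p_CC)")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"posterior probabilities outside [0, 1]: {p}")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"posterior probabilities sum to {p.sum():.6g}, not 1")
    return p


def threshold_posteriors(post: Sequence[float], cutoff: float = 0.9) -> int:
    """Convert a posterior triple (p_BB, p_BC, p_CC) to a hard ancestry call.

    Returns the call whose posterior *strictly* exceeds ``cutoff`` and
    :data:`MISSING` when no state does (a state tying the cutoff exactly is
    treated as not exceeding it).  ``cutoff`` must lie in (1/3, 1] so that at
    most one state can exceed it.
    """
    if not (1.0 / 3.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (1/3, 1]")
    p = _validate_triple(post)
    best = int(np.argmax(p))
    if p[best] > cutoff:
        return best  # index in (BB, BC, CC) order == cortezi allele count
    return MISSING


def threshold_posterior_matrix(posteriors: np.ndarray, cutoff: float = 0.9) -> np.ndarray:
    """Vectorised :func:`threshold_posteriors` over an (..., 3) array."""
    if not (1.0 / 3.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (1/3, 1]")
    p = np.asarray(posteriors, dtype=np.float64)
    if p.shape[-1] != 3:
        raise ValueError("last axis must hold (p_BB, p_BC, p_CC)")
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("malformed posterior triples")
    best = p.argmax(axis=-1)
    out = np.where(np.take_along_axis(p, best[..., None], -1)[..., 0] > cutoff, best, MISSING)
    return out.astype(np.int8)


# ---------------------------------------------------------------------------
# Hybrid index and genotype counts
# ---------------------------------------------------------------------------

def hybrid_index(calls: Iterable[int]) -> HybridIndex:
    """Proportion of cortezi-derived alleles among non-missing calls.

    value = (sum of non-missing calls) / (2 * number of non-missing calls).
    Raises on all-missing input rather than returning 0.
    """
    c = np.asarray(list(calls) if not isinstance(calls, np.ndarray) else calls, dtype=np.int64)
    bad = ~np.isin(c, (0, 1, 2, MISSING))
    if bad.any():
        raise ValueError(f"invalid ancestry call values: {np.unique(c[bad])}")
    ok = c != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("hybrid index undefined: all calls missing")
    return HybridIndex(value=float(c[ok].sum()) / (2.0 * n), n_calls=n)


def hybrid_indices(matrix: AncestryMatrix) -> list[HybridIndex]:
    """Per-individual hybrid index for a whole matrix."""
    return [hybrid_index(row) for row in matrix.calls]


def genotype_counts_at(matrix: AncestryMatrix, marker: int | tuple[str, int]) -> GenotypeCounts:
    """Genotype counts over individuals at one marker.

    ``marker`` is either a column index or a ``(chrom, 1-based pos)`` pair.
    """
    if isinstance(marker, tuple):
        col = matrix.markers.locate(*marker)
    else:
        col = int(marker)
        if not (0 <= col < matrix.markers.n_markers):
            raise KeyError(f"marker column {col} out of range")
    c = matrix.calls[:, col]
    return GenotypeCounts(
        n_CC=int((c == 2).sum()),
        n_BC=int((c == 1).sum()),
        n_BB=int((c == 0).sum()),
        n_missing=int((c == MISSING).sum()),
    )


def pick_representative_site(
    matrix: AncestryMatrix,
    chrom: str,
    start: int,
    end: int,
    seed: int | np.random.Generator = 0,
) -> int:
    """Pick the marker in a 0-based half-open interval covered in the most individuals.

    Ties on missing-call count are broken by a seeded uniform choice, so a
    fixed seed yields a reproducible pick.  Returns the column index.
    """
    cols = matrix.markers.markers_in_interval(chrom, start, end)
    if cols.size == 0:
        raise ValueError(f"no marker overlaps {chrom}:{start}-{end}")
    n_missing = (matrix.calls[:, cols] == MISSING).sum(axis=0)
    best = cols[n_missing == n_missing.min()]
    if best.size == 1:
        return int(best[0])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return int(rng.choice(best))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ancestry_matrix(matrix: AncestryMatrix, path: str | Path) -> None:
    """Write the tab-separated ancestry-matrix format (missing as ``NA``)."""
    m = matrix.markers
    df = pd.DataFrame(
        {
            "chrom": [m.chroms[c] for c in m.chrom_index],
            "pos": m.pos,
        }
    )
    calls = matrix.calls.T.astype(object)
    calls[calls == MISSING] = "NA"
    for j, ind in enumerate(matrix.individuals):
        df[ind] = calls[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_ancestry_matrix(path: str | Path, map_path: str | Path | None = None) -> AncestryMatrix:
    """Read an ancestry-matrix TSV.

    When ``map_path`` is given, per-chromosome lengths come from that marker
    map file; otherwise physical length defaults to the last marker position
    and genetic length to 1 Morgan per chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("ancestry matrix must start with 'chrom' and 'pos' columns")
    individuals = list(df.columns[2:])
    chroms = tuple(dict.fromkeys(df["chrom"]))
    if map_path is not None:
        lengths = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        lengths = lengths.set_index("chrom").loc[list(chroms)]
        length_bp = lengths["length_bp"].to_numpy(dtype=np.int64)
        length_m = lengths["length_morgans"].to_numpy(dtype=np.float64)
    else:
        length_bp = df.groupby("chrom", sort=False)["pos"].max().loc[list(chroms)].to_numpy()
        length_m = np.ones(len(chroms))
    cidx = np.array([chroms.index(c) for c in df["chrom"]], dtype=np.int64)
    mm = MarkerMap(
        chroms=chroms,
        chrom_index=cidx,
        pos=df["pos"].to_numpy(dtype=np.int64),
        length_bp=length_bp,
        length_morgans=length_m,
    )
    calls = df[individuals].to_numpy(dtype=float).T
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return AncestryMatrix(individuals=individuals, markers=mm, calls=calls)


def write_marker_map(m: MarkerMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": list(m.chroms),
            "length_bp": m.length_bp,
            "length_morgans": m.length_morgans,
        }
    ).to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    """Per-chromosome lengths as a DataFrame (chrom, length_bp, length_morgans)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "length_bp", "length_morgans"}
    if not expected.issubset(df.columns):
        raise ValueError(f"marker map file must have columns {sorted(expected)}")
    return df


def read_posteriors(path: str | Path) -> pd.DataFrame:
    """Read the long-format posterior file (chrom, pos, individual, p_BB, p_BC, p_CC)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
    expected = ["chrom", "pos", "individual", "p_BB", "p_BC", "p_CC"]
    if list(df.columns) != expected:
        raise ValueError(f"posterior file must have columns {expected}")
    return df


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write BED3 (0-based half-open) intervals."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            if start < 0 or end < start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\n")
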