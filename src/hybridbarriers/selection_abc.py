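"""Rejection ABC for the strength of selection against X. birchmanni ancestry.

In an F2 intercross the genotype frequencies at fertilization are Mendelian,
(0.25, 0.5, 0.25) for (CC, BC, BB) where B denotes the X. birchmanni allele.
Viability selection against B ancestry with selection coefficient s and
dominance h gives fitnesses w = (1, 1 - h*s, 1 - s); the expected genotype
frequencies among surviving adults are the fitness-weighted Mendelian
frequencies, renormalised.

The ABC draws (s, h) ~ Uniform(0, 1)^2, simulates a cohort of surviving F2s
by a single multinomial draw from the post-selection frequencies, reduces the
cohort to two summary statistics — the mean X. birchmanni ancestry at the
locus and the number of individuals heterozygous or homozygous for B ancestry
— and accepts a draw when both simulated statistics fall within a relative
tolerance (default 5%) of the observed ones.  The accepted draws approximate
the posterior; point estimates are the MAP from a boundary-reflected
Gaussian-kernel density and the central 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry_core import GenotypeCounts

__all__ = [
    "SelectionParams",
    "SummaryStats",
    "PosteriorSample",
    "post_selection_frequencies",
    "draw_cohort",
    "summary_stats",
    "expected_summary_stats",
    "abc_reject",
    "posterior_map_ci",
]

MENDELIAN = np.array([0.25, 0.5, 0.25])  # (CC, BC, BB) at fertilization


@dataclass(frozen=True)
class SelectionParams:
    """Viability selection against X. birchmanni ancestry at one locus.

    Fitnesses are (w_CC, w_BC, w_BB) = (1, 1 - h*s, 1 - s): selection acts
    against the X. birchmanni allele, so the CC homozygote is unaffected.
    """

    s: float
    h: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("selection coefficient s must lie in [0, 1]")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("dominance coefficient h must lie in [0, 1]")

    def fitnesses(self) -> np.ndarray:
        """(w_CC, w_BC, w_BB)."""
        return np.array([1.0, 1.0 - self.h * self.s, 1.0 - self.s])


@dataclass(frozen=True)
class SummaryStats:
    """ABC summary statistics at the focal locus.

    ``mean_b_ancestry`` = (2 n_BB + n_BC) / (2 n); ``n_carriers`` = n_BC +
    n_BB, the number of individuals heterozygous or homozygous for
    X. birchmanni ancestry.
    """

    mean_b_ancestry: float
    n_carriers: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_b_ancestry <= 1.0):
            raise ValueError("mean ancestry must lie in [0, 1]")
        if self.n_carriers < 0:
            raise ValueError("carrier count must be >= 0")


@dataclass(frozen=True)
class PosteriorSample:
    """Accepted (s, h) draws with their rejection-sampling summaries."""

    s: np.ndarray
    h: np.ndarray
    acceptance_rate: float
    map_s: float
    map_h: float
    ci_s: tuple[float, float]
    ci_h: tuple[float, float]

    @property
    def n_accepted(self) -> int:
        return self.s.size


def post_selection_frequencies(params: SelectionParams) -> np.ndarray:
    """Expected adult genotype frequencies (CC, BC, BB) after viability selection.

    f'_g = f_g w_g / sum(f w) with Mendelian f = (0.25, 0.5, 0.25).
    """
    w = params.fitnesses()
    num = MENDELIAN * w
    tot = num.sum()
    if tot <= 0.0:
        raise ValueError("total fitness is zero (s = 1 with h = 1); frequencies undefined")
    return num / tot


def draw_cohort(
    freqs: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> GenotypeCounts:
    """Single multinomial draw of n surviving individuals."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("freqs must be a probability triple (CC, BC, BB)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cc, n_bc, n_bb = rng.multinomial(n, f)
    return GenotypeCounts(n_CC=int(n_cc), n_BC=int(n_bc), n_BB=int(n_bb))


def summary_stats(counts: GenotypeCounts) -> SummaryStats:
    """Reduce genotype counts to the two ABC summary statistics."""
    n = counts.n
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    return SummaryStats(
        mean_b_ancestry=(2.0 * counts.n_BB + counts.n_BC) / (2.0 * n),
        n_carriers=counts.n_BC + counts.n_BB,
    )


def expected_summary_stats(params: SelectionParams, n: int) -> SummaryStats:
    """Expectations of the summary statistics in a cohort of n survivors."""
    f_cc, f_bc, f_bb = post_selection_frequencies(params)
    return SummaryStats(
        mean_b_ancestry=f_bb + 0.5 * f_bc,
        n_carriers=n * (f_bc + f_bb),
    )


def _within(sim: np.ndarray, obs: float, tol: float) -> np.ndarray:
    """Relative-tolerance acceptance; an observed 0 demands an exact 0."""
    if obs == 0.0:
        return sim == 0.0
    return np.abs(sim - obs) <= tol * abs(obs)


def abc_reject(
    observed: SummaryStats | GenotypeCounts,
    n: int,
    n_draws: int = 200_000,
    tolerance: float = 0.05,
    seed: int | np.random.Generator = 0,
    separate_carrier_counts: bool = False,
) -> PosteriorSample:
    """Rejection ABC for (s, h) from observed summary statistics.

    For each draw, (s, h) ~ Uniform(0, 1)^2; a cohort of ``n`` survivors is
    drawn from the post-selection genotype frequencies and reduced to summary
    statistics; the draw is accepted when ALL statistics lie within
    ``tolerance`` (relative) of the observed values (an observed 0 demands an
    exact 0).

    By default the second statistic is the single combined count of B-allele
    carriers (n_BC + n_BB).  With ``separate_carrier_counts=True`` the
    heterozygote and homozygote counts are matched individually instead
    (``observed`` must then be a :class:`GenotypeCounts`); when no BB adults
    were observed this variant is much stricter on weak selection, since any
    simulated BB survivor rejects the draw.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10,000")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if separate_carrier_counts and not isinstance(observed, GenotypeCounts):
        raise TypeError("separate_carrier_counts=True requires observed GenotypeCounts")
    if isinstance(observed, GenotypeCounts):
        obs_counts: GenotypeCounts | None = observed
        observed_stats = summary_stats(observed)
    else:
        obs_counts = None
        observed_stats = observed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = rng.random(n_draws)
    h = rng.random(n_draws)
    w_bc = 1.0 - h * s
    w_bb = 1.0 - s
    tot = 0.25 + 0.5 * w_bc + 0.25 * w_bb
    f_cc, f_bc, f_bb = 0.25 / tot, 0.5 * w_bc / tot, 0.25 * w_bb / tot
    # vectorised multinomial via sequential binomials
    n_cc = rng.binomial(n, f_cc)
    rest = n - n_cc
    p_bc = np.divide(f_bc, 1.0 - f_cc, out=np.zeros_like(f_bc), where=(1.0 - f_cc) > 0)
    n_bc = rng.binomial(rest, np.clip(p_bc, 0.0, 1.0))
    n_bb = rest - n_bc
    sim_mean = (2.0 * n_bb + n_bc) / (2.0 * n)
    ok = _within(sim_mean, observed_stats.mean_b_ancestry, tolerance)
    if separate_carrier_counts:
        assert obs_counts is not None
        ok &= _within(n_bc.astype(float), float(obs_counts.n_BC), tolerance)
        ok &= _within(n_bb.astype(float), float(obs_counts.n_BB), tolerance)
    else:
        ok &= _within(
            (n_bc + n_bb).astype(float), float(observed_stats.n_carriers), tolerance
        )
    n_acc = int(ok.sum())
    if n_acc == 0:
        raise RuntimeError(
            f"rejection ABC accepted 0 of {n_draws} draws at tolerance {tolerance}; "
            f"observed stats (mean={observed_stats.mean_b_ancestry:.4f}, "
            f"carriers={observed_stats.n_carriers}) may be inconsistent with the model "
            "or the tolerance too tight — increase n_draws or tolerance"
        )
    s_acc, h_acc = s[ok], h[ok]
    map_s, ci_s_lo, ci_s_hi = posterior_map_ci(s_acc)
    map_h, ci_h_lo, ci_h_hi = posterior_map_ci(h_acc)
    return PosteriorSample(
        s=s_acc,
        h=h_acc,
        acceptance_rate=n_acc / n_draws,
        map_s=map_s,
        map_h=map_h,
        ci_s=(ci_s_lo, ci_s_hi),
        ci_h=(ci_h_lo, ci_h_hi),
    )


def posterior_map_ci(
    draws: np.ndarray, lo: float = 0.0, hi: float = 1.0
) -> tuple[float, float, float]:
    """MAP and central 95% credible interval of accepted draws on [lo, hi].

    The MAP is the argmax over a 1001-point grid of a Gaussian-kernel density
    with Silverman bandwidth, boundary-reflected at both ends so that modes
    at the edge of the parameter range are not biased inward; the credible
    interval is the 2.5/97.5 percentile pair of the draws.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 50:
        raise ValueError(
            f"only {x.size} accepted draws; need >= 50 for stable summaries — "
            "increase n_draws"
        )
    if hi <= lo:
        raise ValueError("invalid support bounds")
    ci = np.percentile(x, [2.5, 97.5])
    u = (x - lo) / (hi - lo)  # work on [0, 1]
    sd = u.std(ddof=1)
    if sd == 0.0:
        return float(x[0]), float(ci[0]), float(ci[1])
    bw = 0.9 * min(sd, (np.percentile(u, 75) - np.percentile(u, 25)) / 1.34) * u.size ** (
        -0.2
    )
    bw = max(bw, 1e-4)
    grid = np.linspace(0.0, 1.0, 1001)
    # reflect the sample at 0 and 1 to correct boundary bias
    data = np.concatenate([u, -u, 2.0 - u])
    dens = np.zeros(grid.size)
    for block in np.array_split(data, max(1, data.size // 2000)):
        dens += np.exp(-0.5 * ((grid[:, None] - block[None, :]) / bw) ** 2).sum(axis=1)
    map_u = grid[int(np.argmax(dens))]
    return float(lo + map_u * (hi - lo)), float(ci[0]), float(ci[1])
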