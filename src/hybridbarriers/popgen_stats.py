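"""Self-contained statistics for the hybrid-population analyses.

* Pearson goodness-of-fit tests of genotype counts against Mendelian
  expectations,
* Hartigan's dip statistic for unimodality with a uniform-null bootstrap
  p-value (used to establish bimodality of the hybrid-index distribution),
* the two-sided exact binomial test (minimum-likelihood convention),
* the strength-of-preference score for dichotomous female-choice trials with
  the side-bias filter, and
* one-sided Wilcoxon signed-rank tests against a fixed null value.

The dip statistic is computed with the greatest-convex-minorant /
least-concave-majorant construction of Hartigan & Hartigan (1985): the dip of
an empirical distribution function F_n is the smallest sup-norm distance from
F_n to any unimodal distribution function.  Values are invariant to location
and scale; the smallest possible dip for a sample of n distinct values is
1/(2n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ancestry_core import GenotypeCounts

__all__ = [
    "GenotypeCounts",
    "PreferenceTrial",
    "mendelian_chisq",
    "dip_statistic",
    "dip_test",
    "exact_binomial_two_sided",
    "strength_of_preference",
    "side_bias_filter",
    "signed_rank_one_sided",
]

MENDELIAN_F2 = (0.25, 0.5, 0.25)  # (CC, BC, BB) at fertilization in an F2 cross


@dataclass(frozen=True)
class PreferenceTrial:
    """One dichotomous female-choice trial.

    ``t_cortezi`` and ``t_birchmanni`` are association times (seconds) with
    the X. cortezi and X. birchmanni stimulus male; ``side_fractions`` are the
    occupancy fractions of the two tank sides, used only for bias filtering.
    """

    t_cortezi: float
    t_birchmanni: float
    side_fractions: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.t_cortezi < 0 or self.t_birchmanni < 0:
            raise ValueError("association times must be >= 0")
        if any(f < 0 for f in self.side_fractions) or sum(self.side_fractions) > 1 + 1e-9:
            raise ValueError("side occupancy fractions must be >= 0 and sum to <= 1")


def mendelian_chisq(
    counts: GenotypeCounts, expected_props: tuple[float, float, float] = MENDELIAN_F2
) -> tuple[float, int, float]:
    """Pearson chi-squared test of genotype counts against expected proportions.

    ``expected_props`` is ordered (CC, BC, BB) and must sum to 1.  Missing
    calls are excluded (they are not part of ``counts.n``).  Returns
    ``(statistic, df, p_value)`` with df = 2.
    """
    obs = counts.as_array()
    n = counts.n
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    exp = np.asarray(expected_props, dtype=float)
    if exp.shape != (3,) or abs(exp.sum() - 1.0) > 1e-9 or np.any(exp < 0):
        raise ValueError("expected proportions must be a non-negative triple summing to 1")
    if np.any((exp == 0) & (obs > 0)):
        raise ValueError("observed counts in a category with zero expected proportion")
    keep = exp > 0
    stat, p = stats.chisquare(obs[keep], f_exp=n * exp[keep])
    return float(stat), 2, float(p)


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------

def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a sample (sup-norm distance to unimodality).

    Requires ``n >= 4``.  Implemented with the iterative greatest-convex-
    minorant / least-concave-majorant construction; for a sample of distinct
    values the result lies in [1/(2n), 0.25].
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic requires at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if x[0] == x[-1]:
        return 0.0
    return _dip_sorted(x) / (2.0 * n)


def _dip_sorted(xs: np.ndarray) -> float:
    """Dip in count units (final statistic is this / 2n); ``xs`` sorted."""
    n = xs.size
    x = np.empty(n + 1)
    x[1:] = xs  # 1-based indexing to mirror the published construction

    # mn[j]: previous touch point of the greatest convex minorant through
    # (x[i], i); mj[k]: next touch point of the least concave majorant.
    mn = np.empty(n + 1, dtype=np.int64)
    mj = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; a sample of distinct values has dip >= 1
    d = 0.0
    while True:
        # Change points of the GCM (from high down to low) and LCM (low up).
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        ig = l_gcm = len(gcm) - 1
        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        ih = l_lcm = len(lcm) - 1

        # Largest distance d between the two curves, walking both point lists.
        ix, iv = ig - 1, 2
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM: gap measured there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Maximum deviation of the empirical CDF from the GCM on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb + 1, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # ... and from the LCM on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb + 1, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if (new_low, new_high) == (low, high):
            # the candidate modal interval no longer shrinks: no further
            # improvement is possible (covers the perfectly unimodal case
            # where both hulls collapse to straight lines)
            break
        low, high = new_low, new_high
    return max(dip, d)


def dip_test(values, n_boot: int = 1000, seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """One-sided dip test of unimodality, calibrated by uniform bootstrap.

    Returns ``(D, p_value)`` where p is the fraction of uniform(0, 1) samples
    of the same size whose dip is >= the observed dip.  The dip is invariant
    to monotone affine rescaling, so the uniform null is the standard
    calibration.
    """
    x = np.asarray(values, dtype=np.float64)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    d_obs = dip_statistic(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = rng.random((n_boot, x.size))
    boots.sort(axis=1)
    n_ge = sum(_dip_sorted(row) / (2.0 * x.size) >= d_obs for row in boots)
    return d_obs, n_ge / n_boot


# ---------------------------------------------------------------------------
# Exact binomial, preference score, signed-rank
# ---------------------------------------------------------------------------

def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood convention).

    Sums the probabilities of all outcomes whose point probability under
    Binomial(n, p0) does not exceed that of ``k``.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n with n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def strength_of_preference(trial: PreferenceTrial) -> float:
    """(t_cortezi - t_birchmanni) / (t_cortezi + t_birchmanni), in [-1, 1].

    Positive scores indicate preference for the X. cortezi male.  Undefined
    (raises) when the female associated with neither male.
    """
    total = trial.t_cortezi + trial.t_birchmanni
    if total <= 0:
        raise ValueError("strength of preference undefined: zero association time")
    return (trial.t_cortezi - trial.t_birchmanni) / total


def side_bias_filter(trial: PreferenceTrial, cutoff: float = 0.80) -> bool:
    """True (keep) unless the female spent > ``cutoff`` of her time on one side.

    The inequality is strict: a fraction exactly at the cutoff is kept.
    """
    return not any(f > cutoff for f in trial.side_fractions)


def signed_rank_one_sided(
    scores, null_value: float = 0.0, direction: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value against a fixed null value.

    Observations exactly equal to ``null_value`` are dropped (the classic
    zero-handling rule).  The exact distribution is used for n <= 25 when
    ranks are untied; otherwise the normal approximation with tie correction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = np.asarray(scores, dtype=np.float64) - null_value
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all observations equal the null value; test undefined")
    untied = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and untied) else "approx"
    res = stats.wilcoxon(d, alternative=direction, method=method, correction=False)
    return float(res.pvalue)
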