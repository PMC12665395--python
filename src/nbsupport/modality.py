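"""Modality diagnostics for bcl distributions.

A clade torn between conflicting phylogenetic signals (incomplete lineage
sorting, rogue loci, paralogs) shows a *bimodal* subsample bcl distribution:
one peak near 100 from subsamples that support it, one near 0 from
subsamples that favor a conflicting resolution.  This module provides the
two tests used to flag that signature — Hartigan's dip test with Monte
Carlo calibration and Silverman's critical-bandwidth mode-count test — plus
the Wilcoxon signed-rank utility used to compare overconfidence between
groups of clades.

The dip statistic is the maximum distance between the empirical CDF and the
closest unimodal CDF; it is computed by the greatest-convex-minorant /
least-concave-majorant interval-shrinking algorithm on sorted data, and its
null distribution is calibrated by uniform(0,1) samples of matching size.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .support import BclDistribution

__all__ = [
    "ModalityResult",
    "dip_statistic",
    "dip_test",
    "silverman_modes",
    "classify_modality",
    "wilcoxon_signed_rank",
    "rank_sum_test",
]


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(x) -> float:
    """Dip of a sample: max deviation of its ECDF from the nearest unimodal CDF.

    Bounded by 0.25 (attained by an equal two-point mass); bounded below by
    ``1/(2n)`` for non-degenerate samples.  Samples with fewer than 3 points,
    or all points equal, have dip 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    n = x.size
    if n < 3:
        return 0.0
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        return 0.0
    return _dip_sorted(xs)


def _hulls(xsl, lo, hi):
    """Convex minorant / concave majorant touch points of the ECDF on [lo, hi].

    The minorant passes through (x_i, i/n) (ECDF left limits), the majorant
    through (x_i, (i+1)/n) (right limits); within tied x only the extreme
    point can touch, which keeps hull abscissae strictly increasing.
    ``xsl`` is the sorted sample as a plain list (hot path).  Returns the
    touch indices and hull ordinates (count units) as lists.
    """
    firsts, lasts = [lo], []
    prev = xsl[lo]
    for i in range(lo + 1, hi + 1):
        xi = xsl[i]
        if xi != prev:
            firsts.append(i)
            lasts.append(i - 1)
            prev = xi
    lasts.append(hi)

    def build(idx, shift, lower):
        hx, hy, hidx = [], [], []
        for i in idx:
            v = float(i + shift)
            xi = xsl[i]
            while len(hx) >= 2:
                cross = (hx[-1] - hx[-2]) * (v - hy[-2]) - (hy[-1] - hy[-2]) * (
                    xi - hx[-2]
                )
                if (cross <= 0) if lower else (cross >= 0):
                    hx.pop()
                    hy.pop()
                    hidx.pop()
                else:
                    break
            hx.append(xi)
            hy.append(v)
            hidx.append(i)
        return hidx, hy

    g_idx, g_val = build(firsts, 0, lower=True)
    l_idx, l_val = build(lasts, 1, lower=False)
    return g_idx, g_val, l_idx, l_val


def _dip_sorted(xs: np.ndarray) -> float:
    n = len(xs)
    if n < 4:
        return 1.0 / (2 * n)
    xsl = xs.tolist()
    lo, hi = 0, n - 1
    D = 1.0  # in count units; final dip = D / (2n)

    def interp(hx, hy, x):
        k = bisect_right(hx, x) - 1
        if k < 0:
            return hy[0]
        if k >= len(hx) - 1:
            return hy[-1]
        x1, x2 = hx[k], hx[k + 1]
        return hy[k] + (hy[k + 1] - hy[k]) * (x - x1) / (x2 - x1)

    while True:
        g_idx, g_val, l_idx, l_val = _hulls(xsl, lo, hi)
        gx = [xsl[i] for i in g_idx]
        lx = [xsl[i] for i in l_idx]
        # gap between the two hull curves at every touch point
        d = -1.0
        k_best, from_lcm = 0, True
        for k, j in enumerate(l_idx):
            gap = l_val[k] - interp(gx, g_val, lx[k])
            if gap > d:
                d, k_best, from_lcm = gap, k, True
        for k, gpt in enumerate(g_idx):
            gap = interp(lx, l_val, gx[k]) - g_val[k]
            if gap > d:
                d, k_best, from_lcm = gap, k, False
        if d <= D:
            break
        if from_lcm:  # max at a majorant touch point j
            j = l_idx[k_best]
            new_hi = j
            seg = bisect_right(gx, xsl[j]) - 1
            new_lo = g_idx[max(seg, 0)]
        else:  # max at a minorant touch point g
            gpt = g_idx[k_best]
            new_lo = gpt
            seg = bisect_left(lx, xsl[gpt])
            new_hi = l_idx[min(seg, len(l_idx) - 1)]
        new_lo = min(new_lo, new_hi)
        # deviations of the ECDF from the hulls over the discarded flanks
        for i in range(lo, new_lo + 1):
            dev = (i + 1.0) - interp(gx, g_val, xsl[i])
            if dev > D:
                D = dev
        for i in range(new_hi, hi + 1):
            dev = interp(lx, l_val, xsl[i]) - i
            if dev > D:
                D = dev
        if (new_lo, new_hi) == (lo, hi):
            break
        lo, hi = new_lo, new_hi
    return D / (2.0 * n)


def dip_test(
    x,
    n_mc: int = 2000,
    rng: Optional[np.random.Generator] = None,
    null_dips: Optional[np.ndarray] = None,
) -> float:
    """Monte Carlo p-value for the null of a unimodal distribution.

    The reference distribution is the dip of ``n_mc`` uniform(0,1) samples
    of the same size; ``p = (b + 1)/(n_mc + 1)`` where ``b`` counts null
    dips at least as large as observed (the add-one correction avoids
    p = 0).  Precomputed ``null_dips`` (e.g. from :func:`dip_null_table`)
    may be supplied to amortize calibration across many tests.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("dip test requires at least 4 observations")
    d_obs = dip_statistic(x)
    if null_dips is None:
        rng = rng if rng is not None else np.random.default_rng()
        null_dips = dip_null_table(x.size, n_mc, rng)
    null_dips = np.asarray(null_dips, dtype=np.float64)
    b = int(np.sum(null_dips >= d_obs))
    return (b + 1.0) / (null_dips.size + 1.0)


def dip_null_table(
    n: int, n_mc: int = 2000, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Dip statistics of ``n_mc`` uniform(0,1) samples of size ``n``."""
    rng = rng if rng is not None else np.random.default_rng()
    u = np.sort(rng.random((n_mc, n)), axis=1)
    return np.array([_dip_sorted(row) for row in u])


# ---------------------------------------------------------------------------
# Silverman's critical-bandwidth mode-count test
# ---------------------------------------------------------------------------

def _count_modes(x: np.ndarray, h: float, grid: int = 512) -> int:
    """Local maxima of the Gaussian KDE of `x` at bandwidth `h`.

    The grid is refined when the bandwidth is small relative to the data
    span, so narrow modes are never lost between grid points.
    """
    span = np.ptp(x)
    if span > 0 and h < span / (grid / 8):
        grid = min(int(span / h * 8), 4096)
    lo, hi = x.min() - 3 * h, x.max() + 3 * h
    t = np.linspace(lo, hi, grid)
    z = (t[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    # collapse exact plateaus before counting sign changes
    d = np.diff(dens)
    sgn = np.sign(d)
    sgn = sgn[sgn != 0]
    if sgn.size == 0:
        return 1
    flips = np.diff(sgn)
    n_max = int(np.sum(flips < 0))
    if sgn[0] < 0:  # density decreasing from the left edge: mode at edge
        n_max += 1
    return max(n_max, 1)


def critical_bandwidth(x: np.ndarray, k: int, tol: float = 1e-4) -> float:
    """Smallest Gaussian bandwidth giving at most ``k`` KDE modes.

    Relies on the monotone decrease of the Gaussian-KDE mode count in the
    bandwidth; solved by bisection.
    """
    x = np.asarray(x, dtype=np.float64)
    span = x.max() - x.min()
    if span == 0:
        return 0.0
    h_hi = span
    while _count_modes(x, h_hi) > k:
        h_hi *= 2
    # lower bracket stays above the KDE grid resolution
    h_lo = span / 1000.0
    if _count_modes(x, h_lo) <= k:
        return h_lo
    while (h_hi - h_lo) / h_hi > tol:
        h = 0.5 * (h_lo + h_hi)
        if _count_modes(x, h) <= k:
            h_hi = h
        else:
            h_lo = h
    return h_hi


def silverman_modes(
    x,
    k_max: int = 4,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
    alpha: float = 0.05,
) -> int:
    """Smallest number of KDE modes not rejected by the smoothed bootstrap.

    For k = 1, 2, ...: compute the critical bandwidth ``h_k``, draw
    variance-rescaled smoothed-bootstrap samples, and estimate
    ``p = P*(modes at h_k > k)``.  The first k with ``p >= alpha`` is
    returned (``k_max`` if every k below it is rejected).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 5:
        raise ValueError("Silverman test requires at least 5 observations")
    if np.ptp(x) == 0:
        warnings.warn("degenerate (all-equal) sample: one mode", stacklevel=2)
        return 1
    rng = rng if rng is not None else np.random.default_rng()
    n = x.size
    xbar, var = x.mean(), x.var()
    for k in range(1, k_max + 1):
        h = critical_bandwidth(x, k)
        shrink = 1.0 / np.sqrt(1.0 + h * h / var)
        exceed = 0
        for _ in range(n_boot):
            samp = x[rng.integers(0, n, n)]
            y = xbar + (samp - xbar + h * rng.standard_normal(n)) * shrink
            if _count_modes(y, h) > k:
                exceed += 1
        if exceed / n_boot >= alpha:
            return k
    return k_max


# ---------------------------------------------------------------------------
# Putting it together for bcl distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModalityResult:
    """Verdict on one clade's bcl distribution."""

    dip_D: Optional[float]
    dip_p: Optional[float]
    n_modes: Optional[int]
    verdict: str  # unimodal | multimodal | untested
    alpha: float = 0.05


def classify_modality(
    d: BclDistribution,
    alpha: float = 0.05,
    n_mc: int = 2000,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
    null_dips: Optional[np.ndarray] = None,
) -> ModalityResult:
    """Dip test first; if unimodality is rejected, count modes with the
    Silverman test.  Multimodal verdict requires both ``dip_p < alpha`` and
    at least two significant modes.

    bcl values are rescaled to [0, 1] and, because they live on a 100/R
    grid, tied values are jittered by a fixed-seed uniform ±(100/R)/20
    before the dip test (far below the grid spacing) to avoid ECDF
    degeneracy.  Fewer than 4 subsamples → untested.
    """
    if d.S < 4:
        return ModalityResult(None, None, None, "untested", alpha)
    if np.ptp(d.values) <= 100.0 / d.R + 1e-9:
        # all mass within one grid step: modes cannot be resolved below the
        # 100/R support resolution, so the distribution is a single peak
        return ModalityResult(0.0, 1.0, 1, "unimodal", alpha)
    x = np.asarray(d.values, dtype=np.float64) / 100.0
    if np.unique(x).size < x.size:
        jit = np.random.default_rng(181_021_385)  # fixed: determinism contract
        x = x + jit.uniform(-1, 1, x.size) * (1.0 / d.R) / 20.0
    rng = rng if rng is not None else np.random.default_rng(d.S * 100003 + d.R)
    dip_D = dip_statistic(x)
    dip_p = dip_test(x, n_mc=n_mc, rng=rng, null_dips=null_dips)
    n_modes = None
    verdict = "unimodal"
    if dip_p < alpha:
        if np.ptp(x) == 0:
            n_modes = 1
        else:
            n_modes = silverman_modes(x, n_boot=n_boot, rng=rng, alpha=alpha)
        if n_modes >= 2:
            verdict = "multimodal"
    return ModalityResult(float(dip_D), float(dip_p), n_modes, verdict, alpha)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (evaluation utility)
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(diffs) -> float:
    """Two-sided signed-rank p-value for paired differences.

    Zero differences are dropped.  For n <= 25 the p-value is exact —
    dynamic-programming enumeration of all 2^n sign assignments with
    mid-ranked ties (ranks doubled to stay integral) — otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(np.int64)  # doubled mid-ranks
        total = int(r2.sum())
        # distribution of the doubled positive-rank sum under H0
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            new = dist.copy()
            new[r:] += dist[: total + 1 - r]
            dist = new
        dist /= dist.sum()
        w2 = int(np.rint(2 * w_pos))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sigma
    return float(2.0 * sps.norm.sf(abs(z)))


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two unpaired
    groups; companion to the signed-rank test for group comparisons where
    no natural pairing exists."""
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
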