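"""Variance-heterogeneity and mean-effect test statistics.

The Brown-Forsythe test is the median-centered Levene test: each
observation is transformed to its absolute deviation from the group
median, Z_ij = |y_ij - median_j|, and a one-way ANOVA F-ratio is formed
on the Z values,

    W = (N - k) * sum_i N_i (Zbar_i - Zbar_..)^2
        -----------------------------------------
        (k - 1) * sum_i sum_j (Z_ij - Zbar_i)^2

which under the null of equal group variances follows F(k - 1, N - k).
Here k is the number of genotype groups (2 or 3), N_i the group sizes and
Zbar_.. the grand mean of all absolute deviations.  The upper tail of the
F distribution gives the p-value; it is evaluated with the survival
function so that p-values near genome-wide significance (5e-8) do not
lose precision to a 1 - CDF subtraction.

Degenerate inputs (constant groups) make both sums zero; such 0/0 cases
carry a ``degenerate`` flag and an undefined p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["BFResult", "EqtlResult", "brown_forsythe", "bf_matrix", "ols_slope_matrix"]

_EPS = 0.0  # exact-zero test for degenerate sums; deviations are exact floats


@dataclass
class BFResult:
    """Brown-Forsythe test outcome for one grouped sample."""

    statistic: float
    df1: int
    df2: int
    p: float
    group_sizes: tuple
    group_mad: tuple  # per-group mean absolute deviation from the median, Zbar_i
    degenerate: bool = False

    def __iter__(self):  # allows  W, df1, df2, p = result  unpacking in quick scripts
        return iter((self.statistic, self.df1, self.df2, self.p))


@dataclass
class EqtlResult:
    """Additive-model eQTL regression outcome for one variant-gene pair."""

    slope: float
    t_statistic: float
    p: float
    n_used: int
    perfect_fit: bool = False


def brown_forsythe(values_by_group: Sequence[np.ndarray]) -> BFResult:
    """Median-centered Levene (Brown-Forsythe) test of equal variances.

    Parameters
    ----------
    values_by_group : sequence of 1-d arrays
        One array of observations per genotype group; at least two groups,
        each with at least two observations.  Callers enforce any larger
        per-group sample-size rule.

    Returns
    -------
    BFResult
        W, its F degrees of freedom (df1 = k - 1, df2 = N - k), the upper
        tail p-value, per-group sizes and mean absolute deviations.  When
        every absolute deviation is zero within every group the statistic
        is 0/0: the result is flagged degenerate with ``p = nan``.  A zero
        within-group sum with a positive between-group sum yields
        ``W = inf``, ``p = 0`` (also flagged).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("Brown-Forsythe test needs at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two observations")
        if not np.isfinite(g).all():
            raise ValueError(f"group {i} contains non-finite values")

    k = len(groups)
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    zbar = np.empty(k)
    ss_within = 0.0
    z_sum = 0.0
    for i, g in enumerate(groups):
        z = np.abs(g - np.median(g))
        zbar[i] = z.mean()
        ss_within += float(((z - zbar[i]) ** 2).sum())
        z_sum += float(z.sum())
    grand = z_sum / n_total
    ss_between = float((sizes * (zbar - grand) ** 2).sum())
    df1, df2 = k - 1, n_total - k

    if ss_within <= _EPS:
        if ss_between > _EPS:
            return BFResult(math.inf, df1, df2, 0.0, tuple(sizes),
                            tuple(zbar), degenerate=True)
        if z_sum <= _EPS:  # every observation equals its group median: true 0/0
            return BFResult(math.nan, df1, df2, math.nan, tuple(sizes),
                            tuple(zbar), degenerate=True)
        # deviations constant and equal across groups: numerator 0 => W = 0
        return BFResult(0.0, df1, df2, 1.0, tuple(sizes), tuple(zbar))

    w = (n_total - k) * ss_between / ((k - 1) * ss_within)
    p = float(sps.f.sf(w, df1, df2))
    return BFResult(float(w), df1, df2, p, tuple(sizes), tuple(zbar))


def bf_matrix(y: np.ndarray, group_indices: Sequence[np.ndarray]):
    """Vectorized Brown-Forsythe over many response vectors sharing one grouping.

    Parameters
    ----------
    y : (n_genes, n_subjects) array
        Residual expression, one row per gene.
    group_indices : sequence of 1-d integer arrays
        Column indices of each genotype group (already filtered to the
        groups entering the test).

    Returns
    -------
    dict of arrays keyed ``statistic``, ``p``, ``df1``, ``df2``,
    ``group_mad`` ((n_genes, k) Zbar_i), ``degenerate`` (bool mask).
    """
    y = np.asarray(y, dtype=float)
    k = len(group_indices)
    sizes = np.array([len(ix) for ix in group_indices])
    n_total = int(sizes.sum())
    n_genes = y.shape[0]

    zbar = np.empty((n_genes, k))
    ss_within = np.zeros(n_genes)
    z_total = np.zeros(n_genes)
    for i, ix in enumerate(group_indices):
        sub = y[:, ix]
        med = np.median(sub, axis=1, keepdims=True)
        z = np.abs(sub - med)
        zbar[:, i] = z.mean(axis=1)
        ss_within += ((z - zbar[:, i, None]) ** 2).sum(axis=1)
        z_total += z.sum(axis=1)
    grand = z_total / n_total
    ss_between = (sizes[None, :] * (zbar - grand[:, None]) ** 2).sum(axis=1)

    df1, df2 = k - 1, n_total - k
    stat = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    zero_denom = ss_within <= _EPS
    ok = ~zero_denom
    stat[ok] = (n_total - k) * ss_between[ok] / ((k - 1) * ss_within[ok])
    p[ok] = sps.f.sf(stat[ok], df1, df2)
    blown = zero_denom & (ss_between > _EPS)
    stat[blown] = np.inf
    p[blown] = 0.0
    flat = zero_denom & (ss_between <= _EPS) & (z_total > _EPS)
    stat[flat] = 0.0
    p[flat] = 1.0
    degenerate = zero_denom & ~flat
    return {
        "statistic": stat,
        "p": p,
        "df1": df1,
        "df2": df2,
        "group_sizes": sizes,
        "group_mad": zbar,
        "degenerate": degenerate,
    }


def ols_slope_matrix(y: np.ndarray, g: np.ndarray, rss_tol: float = 1e-12):
    """Simple-regression slope of each row of ``y`` on the dosage vector ``g``.

    Closed form: slope = Sxy / Sxx with a two-sided t-test on n - 2
    degrees of freedom.  Rows with a numerically zero residual sum of
    squares are perfect fits: p is reported as 0 with a flag rather than
    dividing by zero.

    Returns a dict of arrays keyed ``slope``, ``t``, ``p``, ``n``,
    ``perfect_fit``.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float).ravel()
    n = g.size
    if y.shape[1] != n:
        raise ValueError("y columns must match genotype vector length")
    if n < 3:
        raise ValueError("need at least three subjects for the t-test")
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx <= 0:
        raise ValueError("genotype vector is constant; no regression possible")
    yc = y - y.mean(axis=1, keepdims=True)
    sxy = yc @ gc
    slope = sxy / sxx
    syy = (yc**2).sum(axis=1)
    rss = syy - slope * sxy
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    dof = n - 2
    scale = np.maximum(syy, 1.0)
    perfect = rss <= rss_tol * scale
    se = np.sqrt(rss / (dof * sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    t = np.where(slope == 0, 0.0, t)
    p = np.where(perfect & (slope != 0), 0.0, 2.0 * sps.t.sf(np.abs(t), dof))
    return {
        "slope": slope,
        "t": t,
        "p": p,
        "n": n,
        "perfect_fit": perfect,
    }
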