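"""Two-group statistics for per-cluster component comparisons.

Pixel distributions of component relative absorbance are compared
between genotypes per (cluster, component) with a Mann-Whitney U test
(image data are not normally distributed) plus a divergence effect size
D — Cohen's standardized mean difference, whose 0.2 / 0.5 / 0.8
small/medium/strong thresholds this convention matches — converted to a
coefficient of determination R^2_D = D^2 / (D^2 + 4). A comparison is
flagged significant when p < p_thresh AND (D > d_thresh OR R^2_D >
r2_thresh); the imaging default is p < 0.001 with D > 0.8 or R^2 > 0.5.

Descriptive statistics follow the boxplot conventions: median,
interquartile range, and QAD (quantile absolute difference — the median
of absolute deviations from the median), with relative differences
expressed as a percentage of the reference group.

The sampling unit is the pixel, not the biological replicate; p-values
therefore carry the usual pseudo-replication caveat of image statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterResult
from .emsc import CubeFit

__all__ = [
    "mann_whitney",
    "effect_size_d",
    "effect_size_d_robust",
    "r2_from_d",
    "qad",
    "relative_difference_pct",
    "area_weighted_mean",
    "pearson",
    "ClusterComparison",
    "compare_clusters",
    "comparisons_to_frame",
]

EXACT_LIMIT = 16  # exact enumeration when n_x + n_y <= this and no ties


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x > y pairs) + 1/2 #(x = y pairs), via midranks (O(n log n))."""
    nx = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p: enumerate all label assignments of the pool."""
    pooled = np.concatenate([x, y])
    n = pooled.size
    nx = x.size
    mu = nx * y.size / 2.0
    dev = abs(u_obs - mu)
    # Midranks are permutation-invariant: U for an assignment is the rank
    # sum of the chosen subset minus nx(nx+1)/2.
    ranks = stats.rankdata(pooled)
    offset = nx * (nx + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(n), nx):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (x vs y) and two-sided p-value.

    ``exact`` enumerates the permutation distribution of U over all
    label assignments (ties handled with the 1/2 convention); ``normal``
    uses the tie-corrected normal approximation with continuity
    correction; ``auto`` picks exact when n_x + n_y <= 16 and the pooled
    data are tie-free.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "normal"
    if mode == "exact":
        return u_obs, _exact_p(x, y, u_obs)
    if mode == "normal":
        if np.ptp(pooled) == 0:
            return u_obs, 1.0  # all values identical: no evidence either way
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return u_obs, float(p)
    raise ValueError(f"unknown mode {mode!r}")


def effect_size_d(x, y) -> float:
    """Divergence effect size: |mean difference| over pooled SD (Cohen's d)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    diff = abs(x.mean() - y.mean())
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means: D = inf", RuntimeWarning)
        return math.inf
    return diff / math.sqrt(pooled_var)


def effect_size_d_robust(x, y) -> float:
    """Robust variant: |median difference| over pooled QAD (1.4826-scaled)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    diff = abs(np.median(x) - np.median(y))
    scale = 1.4826 * math.sqrt((qad(x) ** 2 + qad(y) ** 2) / 2.0)
    if scale == 0:
        return 0.0 if diff == 0 else math.inf
    return diff / scale


def r2_from_d(d: float) -> float:
    """R^2 of the divergence effect size: D^2 / (D^2 + 4).

    Strictly increasing in D; D > 2 is equivalent to R^2 > 0.5.
    """
    if d < 0:
        raise ValueError("D must be nonnegative")
    if math.isinf(d):
        return 1.0
    return d * d / (d * d + 4.0)


def qad(x) -> float:
    """Quantile absolute difference: median of |x_i - median(x)|."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.median(np.abs(x - np.median(x))))


def relative_difference_pct(value_a: float, value_b: float) -> float:
    """Signed percentage difference of a vs reference b: 100 (a - b) / b."""
    if value_b == 0:
        raise ZeroDivisionError("zero reference value")
    return 100.0 * (value_a - value_b) / value_b


def area_weighted_mean(values, areas) -> float:
    """Mean of per-cluster values weighted by cluster pixel areas."""
    values = np.asarray(values, dtype=float).ravel()
    areas = np.asarray(areas, dtype=float).ravel()
    if values.size != areas.size:
        raise ValueError("values and areas length mismatch")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    return float((values * areas).sum() / areas.sum())


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClusterComparison:
    cluster: int
    component: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    qad_a: float
    qad_b: float
    U: float
    p: float
    D: float
    r2_d: float
    rel_diff_pct: float
    verdict: str  # significant | not_significant | undefined


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def compare_clusters(
    fit_a: CubeFit,
    fit_b: CubeFit,
    clusters_a: ClusterResult,
    clusters_b: ClusterResult,
    thresholds: tuple[float, float, float] = (0.001, 0.8, 0.5),
    effect_size: str = "cohen",
    rel_diff_stat: str = "median",
) -> list[ClusterComparison]:
    """One record per (cluster, component): group A vs reference group B.

    Pixel values are component relative absorbances of non-degenerate,
    unmasked pixels. Relative difference uses group medians by default
    (boxplot-consistent), with group B (e.g. the easy-to-root genotype)
    as the 100% reference. A cluster missing in either group yields
    verdict ``undefined``.
    """
    if fit_a.names != fit_b.names:
        raise ValueError("component sets differ between groups")
    if clusters_a.k != clusters_b.k:
        raise ValueError("cluster schemes differ (k mismatch)")
    p_thresh, d_thresh, r2_thresh = thresholds
    d_fun = {"cohen": effect_size_d, "robust": effect_size_d_robust}[effect_size]
    stat_fun = {"median": np.median, "mean": np.mean}[rel_diff_stat]

    valid_a = fit_a.valid_mask()
    valid_b = fit_b.valid_mask()
    records: list[ClusterComparison] = []
    nan = float("nan")
    for cluster in range(1, clusters_a.k + 1):
        in_a = (clusters_a.labels == cluster) & valid_a
        in_b = (clusters_b.labels == cluster) & valid_b
        for j, name in enumerate(fit_a.names):
            xa = fit_a.relative_absorbance[:, :, j][in_a]
            xb = fit_b.relative_absorbance[:, :, j][in_b]
            if xa.size < 2 or xb.size < 2:
                warnings.warn(
                    f"cluster {cluster} missing/too small in one group; verdict undefined",
                    RuntimeWarning,
                )
                records.append(
                    ClusterComparison(
                        cluster, name, xa.size, xb.size,
                        nan, nan, nan, nan, nan, nan,
                        nan, nan, nan, nan, nan, "undefined",
                    )
                )
                continue
            U, p = mann_whitney(xa, xb, mode="auto")
            D = d_fun(xa, xb)
            r2 = r2_from_d(D)
            med_b = float(stat_fun(xb))
            rel = (
                relative_difference_pct(float(stat_fun(xa)), med_b)
                if med_b != 0
                else nan
            )
            significant = (p < p_thresh) and (D > d_thresh or r2 > r2_thresh)
            records.append(
                ClusterComparison(
                    cluster=cluster,
                    component=name,
                    n_a=int(xa.size),
                    n_b=int(xb.size),
                    median_a=float(np.median(xa)),
                    median_b=float(np.median(xb)),
                    iqr_a=_iqr(xa),
                    iqr_b=_iqr(xb),
                    qad_a=qad(xa),
                    qad_b=qad(xb),
                    U=U,
                    p=p,
                    D=D,
                    r2_d=r2,
                    rel_diff_pct=rel,
                    verdict="significant" if significant else "not_significant",
                )
            )
    return records


def comparisons_to_frame(records: list[ClusterComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
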