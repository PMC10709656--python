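"""Group statistics: Kruskal-Wallis with Dunn-Sidak post hoc, box-plot
summaries with the 1.5*IQR outlier rule, and multiple linear regression of
population fractions on the topographic dimensions."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    """Omnibus Kruskal-Wallis result plus the pairwise Dunn table.

    ``pairwise`` has columns group_i, group_j, z, p_raw, p_adjusted (Sidak
    over all k(k-1)/2 comparisons).  ``degenerate`` flags the case where
    every value in every group is identical (H defined as 0, p as 1).
    """

    h_statistic: float
    p_value: float
    group_sizes: list[int]
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False


def _validate_groups(groups):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    return arrays


def kruskal_wallis(groups) -> GroupComparisonResult:
    """Rank-based H test with tie correction; p from the chi-square tail
    with k-1 degrees of freedom.  All-identical data yield H=0, p=1,
    flagged degenerate rather than an error."""
    arrays = _validate_groups(groups)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(
            h_statistic=0.0,
            p_value=1.0,
            group_sizes=[int(a.size) for a in arrays],
            degenerate=True,
        )
    h, p = sps.kruskal(*arrays)
    return GroupComparisonResult(
        h_statistic=float(h), p_value=float(p), group_sizes=[int(a.size) for a in arrays]
    )


def sidak_adjust(p_raw, m: int):
    """Sidak family-wise adjustment 1 - (1 - p)^m; monotone in p."""
    p = np.clip(np.asarray(p_raw, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    return np.where(p >= 1.0, 1.0, adj)


def dunn_sidak_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks with tie correction, adjusted
    by the Sidak rule over m = k(k-1)/2 comparisons."""
    arrays = _validate_groups(groups)
    k = len(arrays)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    else:
        var_base = 0.0
    m = k * (k - 1) // 2
    rows = []
    degenerate = var_base <= 0  # all values identical
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate:
                z, p_raw = 0.0, 1.0
            else:
                se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "z": z,
                    "p_raw": p_raw,
                    "p_adjusted": float(sidak_adjust(p_raw, m)),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(groups, labels=None) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus plus the Dunn-Sidak pairwise table."""
    result = kruskal_wallis(groups)
    result.pairwise = dunn_sidak_posthoc(groups, labels)
    return result


@dataclass
class BoxSummary:
    """Quartiles, whisker bounds and individually flagged outliers under the
    1.5*IQR fence rule (outliers above q3 + 1.5*IQR or below q1 - 1.5*IQR)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def box_summary(values, method: str = "linear") -> BoxSummary:
    """Box-plot summary; ``method`` is the percentile interpolation passed
    to :func:`numpy.percentile` (linear interpolation of the empirical CDF
    by default)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_summary: empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    outliers = v[(v > hi_fence) | (v < lo_fence)]
    inliers = v[(v <= hi_fence) & (v >= lo_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(np.min(inliers)),
        whisker_high=float(np.max(inliers)),
        outliers=np.sort(outliers),
    )


@dataclass
class RegressionResult:
    """OLS fit of a population fraction on the topographic dimensions.

    The model has an intercept (the control fraction, since control rows
    encode G_D = R_w = G_w = 0), main effects for G_D (nm), R_w and G_w
    (µm), and all pairwise products; the three-way product is optional.
    Case 1 restricts to depths 0-725 nm, Case 2 to 0-1000 nm.
    """

    case: int
    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    n_obs: int


_CASE_MAX_DEPTH = {1: 725.0, 2: 1000.0}


def population_regression(
    table: pd.DataFrame,
    case: int = 1,
    response: str = "P",
    include_threeway: bool = False,
) -> RegressionResult:
    """Regress a percentage population on G_D, R_w, G_w and their pairwise
    products (unweighted OLS with intercept).

    ``table`` needs columns ``G_D_nm``, ``R_w_um``, ``G_w_um`` and the
    response.  Raises on rank deficiency or too few rows.
    """
    import statsmodels.api as sm

    if case not in _CASE_MAX_DEPTH:
        raise ValueError(f"case must be 1 or 2, got {case}")
    needed = {"G_D_nm", "R_w_um", "G_w_um", response}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"regression table lacks columns: {sorted(missing)}")
    sub = table[table["G_D_nm"] <= _CASE_MAX_DEPTH[case]].copy()
    x = pd.DataFrame(
        {
            "G_D": sub["G_D_nm"].astype(float),
            "R_w": sub["R_w_um"].astype(float),
            "G_w": sub["G_w_um"].astype(float),
        }
    )
    x["G_D*R_w"] = x["G_D"] * x["R_w"]
    x["G_D*G_w"] = x["G_D"] * x["G_w"]
    x["R_w*G_w"] = x["R_w"] * x["G_w"]
    if include_threeway:
        x["G_D*R_w*G_w"] = x["G_D"] * x["R_w"] * x["G_w"]
    design = sm.add_constant(x, prepend=True)
    if len(sub) < design.shape[1] + 1:
        raise ValueError(
            f"only {len(sub)} rows for {design.shape[1]} parameters; need at least "
            f"{design.shape[1] + 1}"
        )
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear topographic dimensions)")
    y = sub[response].astype(float)
    fit = sm.OLS(y.to_numpy(), design).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst <= 1e-12 * max(1.0, float(np.sum(y**2))) else float(fit.rsquared)
    return RegressionResult(
        case=case,
        coefficients=pd.Series(fit.params.to_numpy(), index=design.columns),
        p_values=pd.Series(fit.pvalues.to_numpy(), index=design.columns),
        r_squared=r2,
        n_obs=int(len(sub)),
    )
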