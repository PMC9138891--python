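"""Feature screening: Friedman tests across levels, Spearman correlations.

Each candidate feature is tested with the nonparametric Friedman test
(subjects as blocks, the three workload levels as treatments, alpha = 0.05);
pairwise monotone association among the 16 retained features is screened
with Spearman's rank correlation.  The sigma parameters are discarded as a
fixed pipeline rule (they are screened for the diagnostic record only).
No multiple-testing correction is applied across the per-feature tests; the
report notes the uncorrected test count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, spearmanr

from .errors import DataError
from .features import FEATURE_NAMES, SIGMA_NAMES, FeatureTable
from .records import LEVELS

__all__ = ["friedman_test", "spearman_corr", "screen_features", "ScreenReport"]

STRONG_CORRELATION_THRESHOLD = 0.8


def friedman_test(values) -> tuple[float, float]:
    """Friedman rank test on an (n_blocks, k_treatments) matrix.

    Within-block average ranks; statistic
    ``chi2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` referred to the
    chi-square distribution with k-1 degrees of freedom.  The plain form is
    used (no tie correction), so a design with all treatments equal in every
    block yields statistic 0 rather than an indeterminate ratio.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DataError("friedman_test expects an (n, k>=2) matrix")
    if arr.shape[0] < 2:
        raise DataError("friedman_test needs at least 2 blocks")
    if not np.all(np.isfinite(arr)):
        raise DataError("friedman_test does not accept missing cells")
    n, k = arr.shape
    ranks = np.apply_along_axis(rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    stat = max(stat, 0.0)  # guard tiny negative round-off
    return stat, float(chi2.sf(stat, k - 1))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("spearman_corr expects two equal-length 1-D series")
    if x.size < 3:
        raise DataError("spearman_corr needs at least 3 observations")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ScreenReport:
    """Friedman screen over all mu/sigma/tau candidates + Spearman matrix."""

    friedman: pd.DataFrame  # feature, statistic, p_value, significant
    spearman_rho: pd.DataFrame  # 16 x 16
    spearman_p: pd.DataFrame
    strong_pairs: pd.DataFrame  # feature_a, feature_b, rho, p_value
    alpha: float
    strong_threshold: float
    notes: dict = field(default_factory=dict)


def _level_matrix(frame: pd.DataFrame, column: str) -> np.ndarray:
    wide = frame.pivot(index="subject", columns="level", values=column)
    wide = wide.reindex(columns=list(LEVELS))
    if wide.isna().any().any():
        raise DataError(f"incomplete design for feature {column}")
    return wide.to_numpy(dtype=float)


def screen_features(
    table: FeatureTable,
    alpha: float = 0.05,
    strong_threshold: float = STRONG_CORRELATION_THRESHOLD,
) -> ScreenReport:
    """Run the full screen on a feature table.

    Friedman results cover all 24 mu/sigma/tau candidates when the table
    carries its sigma diagnostics (16 otherwise); the Spearman matrix covers
    the 16 retained features, flagging pairs with |rho| >= the strong
    threshold at p < alpha.
    """
    frame = table.frame
    candidates = list(FEATURE_NAMES)
    sigma_frame = table.sigma_frame
    rows = []
    for name in candidates:
        stat, p = friedman_test(_level_matrix(frame, name))
        rows.append({"feature": name, "statistic": stat, "p_value": p, "significant": p < alpha})
    if sigma_frame is not None:
        for name in SIGMA_NAMES:
            stat, p = friedman_test(_level_matrix(sigma_frame, name))
            rows.append(
                {"feature": name, "statistic": stat, "p_value": p, "significant": p < alpha}
            )
    friedman = pd.DataFrame(rows)

    k = len(candidates)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    strong = []
    for i in range(k):
        for j in range(i + 1, k):
            r, p = spearman_corr(frame[candidates[i]], frame[candidates[j]])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
            if abs(r) >= strong_threshold and p < alpha:
                strong.append(
                    {"feature_a": candidates[i], "feature_b": candidates[j], "rho": r, "p_value": p}
                )
    spearman_rho = pd.DataFrame(rho, index=candidates, columns=candidates)
    spearman_p = pd.DataFrame(pmat, index=candidates, columns=candidates)
    strong_pairs = pd.DataFrame(strong, columns=["feature_a", "feature_b", "rho", "p_value"])
    return ScreenReport(
        friedman=friedman,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        strong_pairs=strong_pairs,
        alpha=alpha,
        strong_threshold=strong_threshold,
        notes={
            "n_friedman_tests_uncorrected": len(friedman),
            "sigma_discard": "all sigma parameters are dropped as a fixed pipeline rule",
        },
    )
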