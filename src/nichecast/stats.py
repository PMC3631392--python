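"""The inferential toolkit used by the change analysis.

Thin, contract-enforcing wrappers over scipy.stats: Shapiro–Wilk normality
(Royston approximation), paired Student's t, Mann–Whitney U (reported as
min(U_x, U_y), exact null for small samples without ties, tie-corrected
normal approximation otherwise) and the Pearson product-moment correlation.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "shapiro_wilk", "paired_t", "mann_whitney", "pearson"]


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "df": self.df, "p": self.p_value}


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    return arr


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk W and p for 3 ≤ n ≤ 5000; rejects constant samples."""
    arr = _clean(x)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 ≤ n ≤ 5000, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    res = sps.shapiro(arr)
    return TestResult(float(res.statistic), None, float(res.pvalue), "Shapiro-Wilk")


def paired_t(x, y) -> TestResult:
    """Paired Student's t: t = mean(d) / (sd(d)/√n), df = n − 1, two-sided.

    Identical samples give t = 0 (p = 1); constant nonzero differences have
    no defined t and raise.
    """
    ax, ay = _clean(x), _clean(y)
    if ax.shape != ay.shape or ax.size < 2:
        raise ValueError("paired t needs two equal-length samples, n ≥ 2")
    d = ax - ay
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(0.0, ax.size - 1, 1.0, "paired t-test")
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(ax, ay)
    return TestResult(float(res.statistic), ax.size - 1, float(res.pvalue), "paired t-test")


def mann_whitney(x, y, exact_max_n: int = 8) -> TestResult:
    """Mann–Whitney U with midrank ties, U = min(U_x, U_y).

    Exact two-sided p by full enumeration when min(n_x, n_y) ≤ 8 and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    ax, ay = _clean(x), _clean(y)
    if ax.size == 0 or ay.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([ax, ay])).size < ax.size + ay.size
    method = "asymptotic" if has_ties or min(ax.size, ay.size) > exact_max_n else "exact"
    if method == "asymptotic" and np.ptp(np.concatenate([ax, ay])) == 0:
        # all values tied: no ordering information at all
        u_min = ax.size * ay.size / 2
        return TestResult(float(u_min), None, 1.0, "Mann-Whitney U")
    res = sps.mannwhitneyu(ax, ay, alternative="two-sided", method=method,
                           use_continuity=False)
    u_x = float(res.statistic)
    u_min = min(u_x, ax.size * ay.size - u_x)
    return TestResult(u_min, None, float(res.pvalue), "Mann-Whitney U")


def pearson(x, y) -> float:
    """Pearson product-moment correlation in [−1, 1]; n ≥ 3, non-constant."""
    ax, ay = _clean(x), _clean(y)
    if ax.shape != ay.shape or ax.size < 3:
        raise ValueError("pearson needs two equal-length samples, n ≥ 3")
    if np.ptp(ax) == 0 or np.ptp(ay) == 0:
        raise ValueError("pearson undefined for a constant sample")
    return float(sps.pearsonr(ax, ay).statistic)
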