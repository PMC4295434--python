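"""Absolute fit indices: chi-square p and RMSEA with a 90% CI.

RMSEA is noncentrality-based: the population misfit is estimated by
max(0, chi2 - df), and the confidence bounds invert the noncentral
chi-square CDF in its noncentrality parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

__all__ = ["fit_indices", "rmsea_ci"]


def _ncx2_cdf(x: float, df: int, nc: float) -> float:
    if nc <= 0:
        return float(stats.chi2.cdf(x, df))
    return float(stats.ncx2.cdf(x, df, nc))


def _solve_nc(chi_square: float, df: int, target: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2; df, lambda) = target (0 if none)."""
    if _ncx2_cdf(chi_square, df, 0.0) <= target:
        return 0.0
    hi = max(chi_square, df, 1.0)
    while _ncx2_cdf(chi_square, df, hi) > target:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return float(
        optimize.brentq(
            lambda nc: _ncx2_cdf(chi_square, df, nc) - target, 0.0, hi, xtol=1e-10
        )
    )


def rmsea_ci(
    chi_square: float, df: int, n: int, level: float = 0.90
) -> tuple[float, float]:
    """Confidence interval for RMSEA by inverting the noncentral chi-square."""
    alpha = (1.0 - level) / 2.0
    denom = df * (n - 1)
    lam_low = _solve_nc(chi_square, df, 1.0 - alpha)  # CDF = 0.95 at lower bound
    lam_high = _solve_nc(chi_square, df, alpha)  # CDF = 0.05 at upper bound
    return float(np.sqrt(lam_low / denom)), float(np.sqrt(lam_high / denom))


def fit_indices(
    chi_square: float, df: int, n: int
) -> tuple[float, float, tuple[float, float]]:
    """(p_chi, rmsea, rmsea 90% CI) for a fitted covariance-structure model.

    rmsea = sqrt(max(0, chi2 - df) / (df * (n - 1))); a saturated model
    (df = 0) reports rmsea 0 with a degenerate CI.
    """
    if df < 0:
        raise ValueError(f"df must be non-negative, got {df}")
    if df == 0:
        if chi_square > 1e-8:
            raise ValueError(f"df = 0 is inconsistent with chi_square = {chi_square}")
        return 1.0, 0.0, (0.0, 0.0)
    p_chi = float(stats.chi2.sf(chi_square, df))
    rmsea = float(np.sqrt(max(0.0, chi_square - df) / (df * (n - 1))))
    return p_chi, rmsea, rmsea_ci(chi_square, df, n)
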