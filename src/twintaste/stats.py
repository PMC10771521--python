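"""Small statistical helpers shared across the package.

Fisher's r-to-z transformation, confidence intervals for correlations and
standardized effect sizes, and the expected overlap of two random samples
drawn from a finite population.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_z",
    "fisher_z_inverse",
    "pearson_ci",
    "expected_sample_overlap",
    "partial_eta_squared_ci",
    "cohens_d",
    "cohens_d_ci",
]

# |r| = 1 is clipped to this before atanh so z stays finite; callers that
# care can detect clipping via ``was_clipped``.
_R_CLIP = 1.0 - 1e-12


def fisher_z(r, clip: float = _R_CLIP):
    """Fisher z-transform ``z = atanh(r)``.

    Values with |r| >= 1 (possible for degenerate rating vectors) are
    clipped to ``+/-clip`` so the transform stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -clip, clip))
    return out if out.ndim else float(out)


def fisher_z_inverse(z):
    """Inverse Fisher transform ``r = tanh(z)``."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return out if out.ndim else float(out)


def was_clipped(r, clip: float = _R_CLIP) -> bool:
    return bool(np.any(np.abs(np.asarray(r, dtype=float)) > clip))


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Approximate CI for a Pearson correlation via the Fisher transform."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = fisher_z(r)
    se = 1.0 / np.sqrt(n - 3)
    q = sps.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def expected_sample_overlap(n1: int, n2: int, population: int) -> float:
    """Expected number of individuals shared by two random samples.

    Two simple random samples of sizes ``n1`` and ``n2`` drawn without
    replacement from the same population of size ``population`` overlap in
    a hypergeometric number of individuals with mean ``n1 * n2 / population``.
    """
    if not (0 <= n1 <= population and 0 <= n2 <= population):
        raise ValueError("sample sizes must lie within the population size")
    return float(sps.hypergeom(population, n1, n2).mean())


def partial_eta_squared_ci(
    f_stat: float, df1: int, df2: int, level: float = 0.95
) -> tuple[float, float]:
    """CI for partial eta squared by inverting the noncentral-F CDF.

    The noncentrality bounds (lam_lo, lam_hi) solve
    ``P(F_{df1,df2,lam} <= f_obs) = 1 -/+ (1-level)/2`` and map to eta^2
    through ``lam / (lam + df1 + df2 + 1)``.
    """
    alpha = 1 - level

    def _eta(lam: float) -> float:
        return lam / (lam + df1 + df2 + 1)

    def _solve(target_p: float) -> float:
        # cdf decreases in lam; bisect on [0, hi]
        if sps.ncf.cdf(f_stat, df1, df2, 0.0) < target_p:
            return 0.0
        hi = max(10.0, 4 * f_stat * df1)
        while sps.ncf.cdf(f_stat, df1, df2, hi) > target_p:
            hi *= 2
            if hi > 1e8:
                break
        lo = 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if sps.ncf.cdf(f_stat, df1, df2, mid) > target_p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lam_lo = _solve(1 - alpha / 2)
    lam_hi = _solve(alpha / 2)
    return _eta(lam_lo), _eta(lam_hi)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def cohens_d_ci(d: float, nx: int, ny: int, level: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's d by inverting the noncentral-t CDF."""
    alpha = 1 - level
    scale = np.sqrt(1 / nx + 1 / ny)
    t_obs = d / scale
    df = nx + ny - 2

    def _solve(target_p: float) -> float:
        lo, hi = t_obs - 20, t_obs + 20
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if sps.nct.cdf(t_obs, df, mid) > target_p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    return _solve(1 - alpha / 2) * scale, _solve(alpha / 2) * scale
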