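"""Equicoordinate multivariate-normal probabilities and quantiles.

The single-step simultaneous procedures need the scalar z with
P(max_l T_l <= z) = 1 - alpha under a centred multivariate normal law with
correlation matrix R.  The rectangle probability P(all components <= z) is
evaluated with the Genz sequential conditioning algorithm on a scrambled
Sobol point set with a fixed seed, so repeated calls are bit-identical; the
quantile is then found by bracketing root search between the unadjusted and
Bonferroni normal quantiles, which always enclose it.

Comonotone blocks (pairwise correlation 1) are collapsed to a single
representative before factorisation, so the perfectly-correlated limit and
duplicated markers are handled exactly; any other rank deficiency is handled
by a tiny diagonal jitter in the Cholesky factor.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, qmc

__all__ = ["equicoordinate_probability", "equicoordinate_quantile"]

_SOBOL_SEED = 987654321  # fixed: probabilities must be reproducible across runs
_DEFAULT_POINTS = 1 << 14


def _validate_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(R) > 1 + 1e-8):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def _dedupe_comonotone(R: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop components perfectly correlated with an earlier one.

    max(X_1..X_d) is unchanged when a component equals (in law, jointly)
    another, so P(all <= z) only depends on the distinct components.
    """
    d = R.shape[0]
    keep = []
    for j in range(d):
        if all(R[j, k] < 1.0 - tol for k in keep):
            keep.append(j)
    return R[np.ix_(keep, keep)]


def equicoordinate_probability(
    z: float, R: np.ndarray, n_points: int = _DEFAULT_POINTS
) -> float:
    """P(X_1 <= z, ..., X_d <= z) for X ~ N(0, R), deterministic QMC.

    Absolute accuracy is about 1e-6 at the default 2^14 points (d <= 20);
    pass a smaller power of two to trade accuracy for speed.
    """
    R = _dedupe_comonotone(_validate_correlation(R))
    d = R.shape[0]
    if d == 1:
        return float(norm.cdf(z))
    try:
        C = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # rank-deficient but not comonotone: jitter changes P by O(1e-5)
        C = np.linalg.cholesky(R + 1e-9 * np.eye(d))
    w = qmc.Sobol(d - 1, scramble=True, seed=_SOBOL_SEED).random(n_points)
    f = np.full(n_points, norm.cdf(z / C[0, 0]))
    e_prev = f.copy()
    y = np.empty((n_points, d - 1))
    for i in range(1, d):
        u = np.clip(w[:, i - 1] * e_prev, 1e-300, 1 - 1e-16)
        y[:, i - 1] = norm.ppf(u)
        e_prev = norm.cdf((z - y[:, :i] @ C[i, :i]) / C[i, i])
        f = f * e_prev
    return float(f.mean())


def equicoordinate_quantile(
    R: np.ndarray, alpha: float, n_points: int = _DEFAULT_POINTS
) -> float:
    """One-sided equicoordinate (1-alpha) quantile of N(0, R).

    Solves P(all components <= z) = 1 - alpha by Brent root search; the
    solution is bracketed by the unadjusted normal quantile z_{1-alpha}
    (comonotone limit) and the Bonferroni quantile z_{1-alpha/d}
    (independence is already below it).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    R = _dedupe_comonotone(_validate_correlation(R))
    d = R.shape[0]
    lo = norm.ppf(1 - alpha)
    if d == 1:
        return float(lo)
    hi = norm.ppf(1 - alpha / d)
    target = 1 - alpha

    def deficit(z):
        return equicoordinate_probability(z, R, n_points) - target

    f_lo, f_hi = deficit(lo), deficit(hi)
    # QMC noise can push the bracket endpoints marginally past the root
    if f_lo >= 0:
        return float(lo)
    if f_hi <= 0:
        return float(hi)
    return float(brentq(deficit, lo, hi, xtol=1e-7, rtol=1e-12))
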