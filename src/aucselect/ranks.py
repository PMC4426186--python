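"""Midrank/placement machinery behind the nonparametric AUC estimators.

For marker l the AUC is the two-sample ordinal effect
``P(X0 < X1) + 0.5 P(X0 = X1)`` of controls versus cases.  Its rank-form
estimator, the placement representation and the placement-based covariance
estimator of the d-dimensional AUC vector are all computed here.  Ties are
handled exclusively through midranks, which realises the normalised
(mid) distribution-function convention; no jittering or random tie breaking.

The placement of an observation is the empirical distribution function of the
*opposite* group evaluated at that observation.  It is computed from pooled
minus within-group (internal) midranks, which is O(N log N) per marker and
algebraically identical to scanning all case/control pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import BiomarkerData

__all__ = [
    "midranks",
    "RankPlacementTables",
    "CovCorrEstimate",
    "compute_tables",
    "estimate_auc",
    "estimate_cov",
]


def midranks(values) -> np.ndarray:
    """Midranks of a 1-d sample (column-wise for a 2-d array).

    The midrank of a value is (#smaller) + (#equal + 1)/2; tied observations
    share the average of the rank positions they occupy, so ranks always sum
    to n(n+1)/2 per column.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    if np.isnan(values).any():
        raise ValueError("cannot rank NaN values")
    return rankdata(values, method="average", axis=0)


@dataclass(frozen=True)
class RankPlacementTables:
    """Pooled midranks, internal (within-group) ranks and normed placements.

    Attributes
    ----------
    pooled_midranks : (N, d) midranks over both groups combined.
    internal_ranks : (N, d) midranks within each subject's own status group.
    placements : (N, d) normed placements, each in [0, 1]; for a case this is
        the empirical control distribution evaluated at its measurement, and
        vice versa.
    group_placement_means : (2, d); row i is the placement mean of group i.
        Row 1 (cases) equals the AUC estimate, row 0 equals 1 minus it.
    """

    pooled_midranks: np.ndarray
    internal_ranks: np.ndarray
    placements: np.ndarray
    group_placement_means: np.ndarray
    status: np.ndarray


def compute_tables(data: BiomarkerData) -> RankPlacementTables:
    """Rank/placement tables for every marker of a dataset."""
    N = data.n_subjects
    is_case = data.status == 1
    pooled = midranks(data.values)
    internal = np.empty_like(pooled)
    internal[~is_case] = midranks(data.values[~is_case])
    internal[is_case] = midranks(data.values[is_case])
    # placement denominator is the size of the opposite group
    denom = np.where(is_case, data.n_controls, data.n_cases).astype(float)
    placements = (pooled - internal) / denom[:, None]
    means = np.vstack(
        [placements[~is_case].mean(axis=0), placements[is_case].mean(axis=0)]
    )
    return RankPlacementTables(pooled, internal, placements, means, data.status)


def estimate_auc(tables: RankPlacementTables, data: BiomarkerData | None = None) -> np.ndarray:
    """Rank-form AUC estimates, one per marker, each in [0, 1].

    Equals the mean case placement, or equivalently
    ``(mean case rank - mean control rank)/N + 1/2``; unbiased for the
    ordinal effect and invariant under strictly monotone rescaling.
    """
    return tables.group_placement_means[1].copy()


@dataclass(frozen=True)
class CovCorrEstimate:
    """Placement-based covariance/correlation estimate of the AUC vector.

    ``V_hat`` estimates the covariance of sqrt(N) * (AUC-hat - AUC):
    ``V_hat = N (V0/n0 + V1/n1)`` with ``Vi`` the sample covariance of the
    group-i placements.  A marker whose AUC estimate is exactly 0 or 1 has
    constant placements, hence a zero variance estimate; such markers are
    flagged ``degenerate`` rather than raising, so callers can decide on the
    boundary policy.
    """

    V_hat: np.ndarray
    V_hat_group: tuple
    R_hat: np.ndarray
    degenerate: np.ndarray

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.V_hat).copy()


def estimate_cov(tables: RankPlacementTables, data: BiomarkerData) -> CovCorrEstimate:
    """Covariance and correlation estimates from the placement tables."""
    n0, n1 = data.n_controls, data.n_cases
    N = n0 + n1
    is_case = tables.status == 1
    Z0 = tables.placements[~is_case]
    Z1 = tables.placements[is_case]
    V0 = np.atleast_2d(np.cov(Z0, rowvar=False, ddof=1))
    V1 = np.atleast_2d(np.cov(Z1, rowvar=False, ddof=1))
    V = N * (V0 / n0 + V1 / n1)
    v = np.diag(V)
    degenerate = v <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(v > 0, 1.0 / np.sqrt(np.where(v > 0, v, 1.0)), np.nan)
        R = V * np.outer(scale, scale)
    # exact unit diagonal where defined
    np.fill_diagonal(R, np.where(degenerate, np.nan, 1.0))
    R = np.clip(R, -1.0, 1.0, out=R)
    return CovCorrEstimate(V, (V0, V1), R, degenerate)
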