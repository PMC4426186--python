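"""Wild-bootstrap approximation of the joint null law of the max statistic.

Asymptotic equicoordinate quantiles are unreliable for small samples and
accuracies near 1.  The wild bootstrap multiplies the *centred placements*
of every subject by i.i.d. mean-0/variance-1 random weights, recomputes the
studentised contrast per marker, and uses the empirical distribution of the
maximum over markers as the reference law.  Conditionally on the data this
reproduces the joint limit distribution of the statistics under null and
alternative alike, so it can be used both for p-values and for simultaneous
confidence bounds (on the logit scale, where convergence is fastest).

Algorithm per draw: generate weights W_is, form Z*_is = W_is (Z_is - Zbar_i.),
studentise the group-mean contrast per marker, record the max over markers.
The (1-alpha) empirical quantile of the recorded maxima replaces the
multivariate-normal equicoordinate quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data import BiomarkerData
from .inference import (
    AUCInferenceResults,
    InferenceConfig,
    _check_nondegenerate,
    logit_statistics,
    select_markers,
)
from .ranks import CovCorrEstimate, RankPlacementTables, compute_tables, estimate_auc, estimate_cov

__all__ = [
    "WeightScheme",
    "BootstrapDraws",
    "generate_weights",
    "bootstrap_statistics",
    "wb_inference",
    "efron_bootstrap_inference",
]

WEIGHT_KINDS = ("rademacher", "normal", "uniform")
_MAX_REDRAWS = 100
_SQRT3 = np.sqrt(3.0)  # uniform weights live on [-sqrt(12)/2, sqrt(12)/2]


@dataclass(frozen=True)
class WeightScheme:
    """Law of the wild-bootstrap multipliers (mean 0, variance 1)."""

    kind: str = "normal"
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}; choose from {WEIGHT_KINDS}")


@dataclass(frozen=True)
class BootstrapDraws:
    """Recorded max statistics A*_j and the empirical critical value."""

    max_stats: np.ndarray
    quantile: float
    nboot: int
    scheme: WeightScheme


def generate_weights(n, scheme: WeightScheme, rng: np.random.Generator | None = None):
    """Draw i.i.d. weights of the given law; `n` may be an int or a shape."""
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "rademacher":
        return rng.integers(0, 2, size=n).astype(float) * 2.0 - 1.0
    if scheme.kind == "normal":
        return rng.standard_normal(size=n)
    return rng.uniform(-_SQRT3, _SQRT3, size=n)


def _centered_group_placements(tables: RankPlacementTables):
    is_case = tables.status == 1
    Z0 = tables.placements[~is_case]
    Z1 = tables.placements[is_case]
    return Z0 - Z0.mean(axis=0), Z1 - Z1.mean(axis=0)


def bootstrap_statistics(
    tables: RankPlacementTables,
    weights: np.ndarray,
    denominator: str = "consistent",
) -> np.ndarray:
    """Studentised wild-bootstrap statistics T* for one or many draws.

    ``weights`` has shape (N,) or (nboot, N), subject order controls first
    then cases.  The variance in the denominator combines the group-wise
    empirical variances of the weighted centred placements as
    v*_0/n_0 + v*_1/n_1 (``"consistent"``, matching the pairing of the
    covariance estimator); ``"as_printed"`` selects the cross-paired variant
    v*_1/n_0 + v*_0/n_1 for comparison.
    """
    if denominator not in ("consistent", "as_printed"):
        raise ValueError("denominator must be 'consistent' or 'as_printed'")
    Zc0, Zc1 = _centered_group_placements(tables)
    n0, n1 = Zc0.shape[0], Zc1.shape[0]
    N = n0 + n1
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[1] != N:
        raise ValueError(f"need one weight per subject ({N}), got shape {W.shape}")
    W0, W1 = W[:, :n0], W[:, n0:]
    M0 = (W0 @ Zc0) / n0
    M1 = (W1 @ Zc1) / n1
    S0 = (W0**2) @ (Zc0**2)
    S1 = (W1**2) @ (Zc1**2)
    v0 = (S0 - n0 * M0**2) / (n0 - 1)
    v1 = (S1 - n1 * M1**2) / (n1 - 1)
    if denominator == "consistent":
        denom = v0 / n0 + v1 / n1
    else:
        denom = v1 / n0 + v0 / n1
    # the denominator already estimates Var(M1 - M0 | data), so the ratio is
    # conditionally standardised as it stands
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (M1 - M0) / np.sqrt(denom)
    T[~np.isfinite(T)] = np.nan
    return T if np.asarray(weights).ndim > 1 else T[0]


def _draw_max_stats(
    tables: RankPlacementTables,
    nboot: int,
    scheme: WeightScheme,
    rng: np.random.Generator,
    denominator: str = "consistent",
) -> np.ndarray:
    """nboot max-over-markers statistics; degenerate draws are redrawn."""
    N = tables.placements.shape[0]
    T = bootstrap_statistics(tables, generate_weights((nboot, N), scheme, rng), denominator)
    A = T.max(axis=1)
    for _ in range(_MAX_REDRAWS):
        bad = ~np.isfinite(T).all(axis=1)
        if not bad.any():
            return A
        W = generate_weights((int(bad.sum()), N), scheme, rng)
        T[bad] = bootstrap_statistics(tables, W, denominator)
        A[bad] = T[bad].max(axis=1)
    raise RuntimeError(
        "wild bootstrap: degenerate draws persisted after "
        f"{_MAX_REDRAWS} redraw rounds (constant placements?)"
    )


def empirical_quantile(max_stats: np.ndarray, alpha: float) -> float:
    """Higher-order-statistic (1-alpha) quantile: the ceil((1-a) nboot)-th value."""
    nboot = len(max_stats)
    k = int(np.ceil((1 - alpha) * nboot))
    k = min(max(k, 1), nboot)
    return float(np.sort(max_stats)[k - 1])


def wb_inference(
    data: BiomarkerData,
    tables: RankPlacementTables | None = None,
    cov: CovCorrEstimate | None = None,
    config: InferenceConfig | None = None,
    *,
    denominator: str = "consistent",
) -> AUCInferenceResults:
    """Full wild-bootstrap screening analysis.

    Per-marker p-value: 1 minus the retention proportion
    (1/nboot) sum_j I{T-tilde_l >= A*_j} (ties retained), so small p means
    strong evidence; marker selected when T-tilde_l >= z*_{1-alpha}; the
    confidence bound is the logit-scale bound with z* in place of the
    multivariate-normal quantile.  Identical (data, seed, nboot, scheme)
    give bit-identical output.
    """
    if config is None:
        raise ValueError("config is required")
    if tables is None:
        tables = compute_tables(data)
    if cov is None:
        cov = estimate_cov(tables, data)
    if config.nboot < 1:
        raise ValueError("nboot must be >= 1")
    auc_hat = estimate_auc(tables)
    _check_nondegenerate(cov.variances, data.marker_names)
    N = data.n_subjects
    t_logit, s_diag = logit_statistics(auc_hat, cov.variances, config.auc0, N)

    scheme = WeightScheme(config.weights, config.seed)
    rng = np.random.default_rng(config.seed)
    A = _draw_max_stats(tables, config.nboot, scheme, rng, denominator)
    z_star = empirical_quantile(A, config.alpha)
    retention = (t_logit[:, None] >= A[None, :]).mean(axis=1)
    p_values = 1.0 - retention
    lower = expit(logit(auc_hat) - z_star * np.sqrt(s_diag / N))
    draws = BootstrapDraws(A, z_star, config.nboot, scheme)
    return select_markers(
        auc_hat,
        t_logit,
        z_star,
        lower,
        p_values,
        config,
        data.marker_names,
        cov=cov,
        nboot=config.nboot,
        weights=config.weights,
        seed=config.seed,
        bootstrap=draws,
    )


def _efron_max_stats(x0, x1, g_hat, nboot, rng):
    """Vectorised batch of Efron max statistics; degenerate draws come back NaN."""
    from scipy.stats import rankdata as _rankdata

    n0, n1 = x0.shape[0], x1.shape[0]
    N = n0 + n1
    X0 = x0[rng.integers(0, n0, size=(nboot, n0))]
    X1 = x1[rng.integers(0, n1, size=(nboot, n1))]
    pooled = _rankdata(np.concatenate([X0, X1], axis=1), method="average", axis=1)
    Z0 = (pooled[:, :n0] - _rankdata(X0, method="average", axis=1)) / n1
    Z1 = (pooled[:, n0:] - _rankdata(X1, method="average", axis=1)) / n0
    auc = Z1.mean(axis=1)
    v = N * (np.var(Z0, axis=1, ddof=1) / n0 + np.var(Z1, axis=1, ddof=1) / n1)
    ok = (v > 0).all(axis=1) & ((auc > 0) & (auc < 1)).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = v / (auc * (1 - auc)) ** 2
        T = (logit(auc) - g_hat) * np.sqrt(N / s)
    A = T.max(axis=1)
    A[~ok] = np.nan
    return A


def efron_bootstrap_inference(
    data: BiomarkerData,
    config: InferenceConfig,
    nboot: int | None = None,
    seed: int | None = None,
) -> AUCInferenceResults:
    """Conventional (Efron) case-resampling bootstrap, for comparison only.

    Controls and cases are resampled with replacement within their groups;
    per draw the logit-scale studentised statistic centred at the original
    estimates is computed and the max over markers recorded.  Resamples with
    a boundary AUC or zero variance are redrawn.  This procedure is known to
    be anti-conservative for high accuracies and small samples.
    """
    nboot = config.nboot if nboot is None else nboot
    seed = config.seed if seed is None else seed
    tables = compute_tables(data)
    cov = estimate_cov(tables, data)
    auc_hat = estimate_auc(tables)
    _check_nondegenerate(cov.variances, data.marker_names)
    N = data.n_subjects
    t_logit, s_diag = logit_statistics(auc_hat, cov.variances, config.auc0, N)
    g_hat = logit(auc_hat)

    rng = np.random.default_rng(seed)
    x0, x1 = data.controls, data.cases
    n0, n1 = x0.shape[0], x1.shape[0]
    A = np.full(nboot, np.nan)
    todo = np.arange(nboot)
    for _ in range(_MAX_REDRAWS + 1):
        A[todo] = _efron_max_stats(x0, x1, g_hat, len(todo), rng)
        todo = np.flatnonzero(~np.isfinite(A))
        if todo.size == 0:
            break
    else:
        raise RuntimeError("Efron bootstrap: persistent degenerate resamples")
    z_star = empirical_quantile(A, config.alpha)
    p_values = 1.0 - (t_logit[:, None] >= A[None, :]).mean(axis=1)
    lower = expit(g_hat - z_star * np.sqrt(s_diag / N))
    draws = BootstrapDraws(A, z_star, nboot, WeightScheme("normal", seed))
    return select_markers(
        auc_hat,
        t_logit,
        z_star,
        lower,
        p_values,
        config,
        data.marker_names,
        cov=cov,
        nboot=nboot,
        weights=None,
        seed=seed,
        bootstrap=draws,
        extras={"procedure": "efron"},
    )
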