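"""Simultaneous one-sided tests and confidence bounds for AUC vectors.

Every marker is screened against a pre-specified non-inferiority threshold
``auc0``: the marker is *selected* when its one-sided simultaneous lower
confidence bound exceeds the threshold, equivalently when its studentised
statistic reaches the procedure's critical value.  Available single-step
procedures:

``unadjusted``   per-marker normal quantile z_{1-alpha} (no multiplicity
                 control; kept for comparison),
``bonferroni``   normal quantile z_{1-alpha/d},
``mcp``          multiple contrast test: equicoordinate quantile of
                 N(0, R-hat), on the raw AUC scale,
``logit``        the same equicoordinate quantile applied to
                 logit-transformed estimates (delta method), which converges
                 faster for accuracies near the boundary,
``wb``           wild-bootstrap estimate of that quantile (small samples);
                 implemented in :mod:`aucselect.wild_bootstrap`.

All procedures are compatible in the single-step sense: the test decision and
the confidence-bound decision coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .data import BiomarkerData
from .mvnorm import equicoordinate_probability, equicoordinate_quantile
from .ranks import CovCorrEstimate

__all__ = [
    "InferenceConfig",
    "DegenerateMarkerError",
    "AUCInferenceResults",
    "test_statistics",
    "logit_statistics",
    "ci_unadjusted",
    "ci_bonferroni",
    "ci_mcp",
    "ci_logit",
    "apply_boundary_fix",
    "select_markers",
]

METHODS = ("unadjusted", "bonferroni", "mcp", "logit", "wb")


class DegenerateMarkerError(ValueError):
    """A marker's estimated AUC is 0 or 1, so its variance estimate vanishes."""


@dataclass(frozen=True)
class InferenceConfig:
    """Analysis settings.

    alpha defaults to 0.025 one-sided (the regulatory one-sided 97.5%
    confidence-interval convention for non-inferiority).
    """

    auc0: float
    alpha: float = 0.025
    method: str = "wb"
    boundary_policy: str = "error"  # or "boundary_fix"
    weights: str = "normal"  # wild-bootstrap weight law
    nboot: int = 10_000
    seed: int | None = None
    quantile_points: int = 1 << 14

    def __post_init__(self):
        if not 0 < self.auc0 < 1:
            raise ValueError("auc0 must lie in (0, 1)")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5) (one-sided level)")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.boundary_policy not in ("error", "boundary_fix"):
            raise ValueError("boundary_policy must be 'error' or 'boundary_fix'")


def _check_nondegenerate(variances, marker_names):
    bad = np.flatnonzero(np.asarray(variances) <= 0.0)
    if bad.size:
        names = ", ".join(marker_names[b] for b in bad)
        raise DegenerateMarkerError(
            f"marker(s) {names} have estimated AUC 0 or 1 (zero variance "
            "estimate); the statistics cannot be computed. Re-run with "
            "boundary_policy='boundary_fix' to apply the conservative "
            "data modification."
        )


def test_statistics(auc_hat, variances, auc0: float, N: int) -> np.ndarray:
    """Studentised raw-scale statistics T_l = (AUC-hat_l - auc0) sqrt(N/v_ll)."""
    auc_hat = np.asarray(auc_hat, dtype=float)
    variances = np.asarray(variances, dtype=float)
    return (auc_hat - auc0) * np.sqrt(N / variances)


def logit_statistics(auc_hat, variances, auc0: float, N: int):
    """Logit-scale statistics and the transformed variance diagonal.

    The delta method maps the AUC-scale variance v_ll to
    s_ll = v_ll / (AUC-hat_l (1 - AUC-hat_l))^2; the statistic compares
    logit(AUC-hat) with logit(auc0).
    """
    auc_hat = np.asarray(auc_hat, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.any((auc_hat <= 0) | (auc_hat >= 1)):
        raise DegenerateMarkerError(
            "logit transform undefined for AUC estimates at 0 or 1"
        )
    s_diag = variances / (auc_hat * (1 - auc_hat)) ** 2
    t = (logit(auc_hat) - logit(auc0)) * np.sqrt(N / s_diag)
    return t, s_diag


def ci_unadjusted(auc_hat, variances, N: int, alpha: float) -> np.ndarray:
    """Per-marker one-sided lower bounds at local level alpha (no adjustment)."""
    z = norm.ppf(1 - alpha)
    lb = np.asarray(auc_hat) - z * np.sqrt(np.asarray(variances) / N)
    return np.clip(lb, 0.0, 1.0)


def ci_bonferroni(auc_hat, variances, N: int, alpha: float) -> np.ndarray:
    """Bonferroni simultaneous lower bounds (normal quantile at alpha/d)."""
    d = len(np.atleast_1d(auc_hat))
    return ci_unadjusted(auc_hat, variances, N, alpha / d)


def ci_mcp(auc_hat, variances, R_hat, N: int, alpha: float, *, z=None,
           quantile_points: int = 1 << 14) -> np.ndarray:
    """Multiple-contrast simultaneous lower bounds on the raw AUC scale."""
    if z is None:
        z = equicoordinate_quantile(R_hat, alpha, quantile_points)
    lb = np.asarray(auc_hat) - z * np.sqrt(np.asarray(variances) / N)
    return np.clip(lb, 0.0, 1.0)


def ci_logit(auc_hat, s_diag, R_hat, N: int, alpha: float, *, z=None,
             quantile_points: int = 1 << 14) -> np.ndarray:
    """Logit-scale simultaneous lower bounds, mapped back with expit."""
    if z is None:
        z = equicoordinate_quantile(R_hat, alpha, quantile_points)
    return expit(logit(np.asarray(auc_hat)) - z * np.sqrt(np.asarray(s_diag) / N))


def apply_boundary_fix(data: BiomarkerData, marker: int) -> BiomarkerData:
    """Conservative data modification for a marker at the AUC boundary.

    At AUC-hat = 1 the largest control measurement is replaced by the
    smallest case measurement (creating one tie); at AUC-hat = 0, mirrored,
    the smallest case measurement is replaced by the largest control one.
    The effect is decreased and the variance increased, so decisions can
    only become more conservative.  A non-degenerate marker is returned
    unchanged with a warning.
    """
    from .ranks import compute_tables, estimate_auc  # local: avoid cycle at import

    tables = compute_tables(data)
    auc = estimate_auc(tables)[marker]
    if not (auc == 0.0 or auc == 1.0):
        warnings.warn(
            f"marker {data.marker_names[marker]!r} is not at the AUC boundary "
            f"(estimate {auc:.4f}); data left unchanged",
            stacklevel=2,
        )
        return data
    values = data.values.copy()
    controls = np.flatnonzero(data.status == 0)
    cases = np.flatnonzero(data.status == 1)
    col = values[:, marker]
    if auc == 1.0:
        donor = col[cases].min()
        target = controls[np.argmax(col[controls])]
    else:
        donor = col[controls].max()
        target = cases[np.argmin(col[cases])]
    values[target, marker] = donor
    return BiomarkerData(values, data.status, data.marker_names)


@dataclass
class AUCInferenceResults:
    """Results of a simultaneous AUC screening analysis.

    The selection flag of marker l is ``statistics[l] >= critical_value``,
    which coincides with ``lower_bounds[l] > auc0`` (single-step
    compatibility); ``global_reject`` is true when any marker is selected.
    """

    method: str
    auc0: float
    alpha: float
    marker_names: tuple
    auc_hat: np.ndarray
    statistics: np.ndarray
    critical_value: float
    lower_bounds: np.ndarray
    p_values: np.ndarray | None
    selected: np.ndarray
    global_reject: bool
    cov: CovCorrEstimate | None = None
    boundary_fixed: tuple = ()
    nboot: int | None = None
    weights: str | None = None
    seed: int | None = None
    bootstrap: object | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker": list(self.marker_names),
                "auc": self.auc_hat,
                "lower_bound": self.lower_bounds,
                "p_adj": self.p_values if self.p_values is not None else np.nan,
                "statistic": self.statistics,
                "selected": self.selected,
            }
        )
        return df

    def summary(self) -> str:
        head = (
            f"Simultaneous one-sided AUC inference ({self.method})\n"
            f"  H0: AUC <= {self.auc0:g}   alpha = {self.alpha:g} (one-sided)\n"
            f"  critical value: {self.critical_value:.4f}"
        )
        if self.method == "wb":
            head += f"   [wild bootstrap, {self.weights} weights, nboot={self.nboot}]"
        if self.boundary_fixed:
            names = ", ".join(self.marker_names[m] for m in self.boundary_fixed)
            head += f"\n  boundary fix applied to: {names}"
        body = self.summary_frame().to_string(
            index=False, float_format=lambda v: f"{v:.4f}"
        )
        tail = (
            f"global H0 rejected: {self.global_reject} "
            f"({self.n_selected} of {len(self.marker_names)} markers selected)"
        )
        return f"{head}\n\n{body}\n\n{tail}\n"

    def __str__(self):
        return self.summary()


def adjusted_p_values(method, statistics, R_hat, d, quantile_points=1 << 14):
    """Single-step adjusted p-values consistent with the CI decisions."""
    statistics = np.asarray(statistics, dtype=float)
    if method == "unadjusted":
        return 1 - norm.cdf(statistics)
    if method == "bonferroni":
        return np.minimum(1.0, d * (1 - norm.cdf(statistics)))
    # mcp / logit: p_l = P(max of N(0, R-hat) > t_l)
    return np.array(
        [
            1 - equicoordinate_probability(t, R_hat, quantile_points)
            for t in statistics
        ]
    )


def select_markers(
    auc_hat,
    statistics,
    critical_value: float,
    lower_bounds,
    p_values,
    config: InferenceConfig,
    marker_names,
    cov: CovCorrEstimate | None = None,
    **meta,
) -> AUCInferenceResults:
    """Assemble results and verify test/CI compatibility.

    The decision is taken from the statistics; the lower-bound decision is
    checked against it (they can only differ on an exact tie, which has
    probability zero for continuous data and is tolerated to float precision).
    """
    statistics = np.asarray(statistics, dtype=float)
    lower_bounds = np.asarray(lower_bounds, dtype=float)
    selected = statistics >= critical_value
    ci_selected = lower_bounds > config.auc0
    disagree = selected != ci_selected
    if np.any(disagree):
        # only exact boundary ties may disagree
        gap = np.abs(statistics[disagree] - critical_value)
        if np.any(gap > 1e-8):
            raise AssertionError(
                "test and confidence-bound decisions disagree beyond a "
                f"boundary tie (|T - z| up to {gap.max():.3e})"
            )
    return AUCInferenceResults(
        method=config.method,
        auc0=config.auc0,
        alpha=config.alpha,
        marker_names=tuple(marker_names),
        auc_hat=np.asarray(auc_hat, dtype=float),
        statistics=statistics,
        critical_value=float(critical_value),
        lower_bounds=lower_bounds,
        p_values=None if p_values is None else np.asarray(p_values, dtype=float),
        selected=selected,
        global_reject=bool(selected.any()),
        cov=cov,
        **meta,
    )
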