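"""Model/Results front-end for simultaneous AUC non-inferiority screening.

Usage::

    model = AUCNonInferiority(data, auc0=0.8)          # data: BiomarkerData
    res = model.fit(method="wb", seed=1)               # AUCInferenceResults
    print(res.summary())

or from a DataFrame / CSV file with a status column::

    model = AUCNonInferiority.from_dataframe(df, status_column="disease",
                                             control_label="no", case_label="yes",
                                             auc0=0.8)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BiomarkerData, read_biomarker_csv
from .inference import (
    AUCInferenceResults,
    InferenceConfig,
    _check_nondegenerate,
    adjusted_p_values,
    apply_boundary_fix,
    ci_bonferroni,
    ci_logit,
    ci_mcp,
    ci_unadjusted,
    logit_statistics,
    select_markers,
    test_statistics,
)
from .mvnorm import equicoordinate_quantile
from .ranks import compute_tables, estimate_auc, estimate_cov
from scipy.stats import norm

__all__ = ["AUCNonInferiority"]


class AUCNonInferiority:
    """Screen d diagnostic tests against a non-inferiority AUC threshold.

    Parameters
    ----------
    data : BiomarkerData
        Paired measurements of every marker on every subject plus the
        binary gold standard.
    auc0 : float
        Non-inferiority margin; a marker is selected when its simultaneous
        one-sided lower confidence bound exceeds it.
    alpha : float
        One-sided familywise level, default 0.025.
    """

    def __init__(self, data: BiomarkerData, auc0: float, alpha: float = 0.025):
        if not isinstance(data, BiomarkerData):
            data = BiomarkerData(np.asarray(data), np.zeros(len(data)))
        self.data = data
        self.auc0 = float(auc0)
        self.alpha = float(alpha)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        auc0: float,
        status_column: str = "status",
        control_label="0",
        case_label="1",
        alpha: float = 0.025,
    ) -> "AUCNonInferiority":
        data = BiomarkerData.from_frame(df, status_column, control_label, case_label)
        return cls(data, auc0, alpha)

    @classmethod
    def from_csv(
        cls,
        path,
        auc0: float,
        status_column: str = "status",
        control_label="0",
        case_label="1",
        alpha: float = 0.025,
    ) -> "AUCNonInferiority":
        data = read_biomarker_csv(path, status_column, control_label, case_label)
        return cls(data, auc0, alpha)

    def fit(
        self,
        method: str = "wb",
        boundary_policy: str = "error",
        weights: str = "normal",
        nboot: int = 10_000,
        seed: int | None = None,
        quantile_points: int = 1 << 14,
    ) -> AUCInferenceResults:
        """Run the chosen simultaneous procedure and return results.

        method : "unadjusted", "bonferroni", "mcp", "logit" or "wb".
        boundary_policy : "error" (default) or "boundary_fix"; the latter
            applies the conservative tie-creating modification to every
            marker whose AUC estimate sits exactly at 0 or 1.
        """
        config = InferenceConfig(
            auc0=self.auc0,
            alpha=self.alpha,
            method=method,
            boundary_policy=boundary_policy,
            weights=weights,
            nboot=nboot,
            seed=seed,
            quantile_points=quantile_points,
        )
        return analyze(self.data, config)


def analyze(data: BiomarkerData, config: InferenceConfig) -> AUCInferenceResults:
    """Function form of :meth:`AUCNonInferiority.fit`."""
    from .wild_bootstrap import wb_inference  # deferred: avoid import cycle

    tables = compute_tables(data)
    cov = estimate_cov(tables, data)
    fixed: list[int] = []
    if config.boundary_policy == "boundary_fix" and cov.degenerate.any():
        auc = estimate_auc(tables)
        for m in np.flatnonzero(cov.degenerate):
            if auc[m] in (0.0, 1.0):
                data = apply_boundary_fix(data, int(m))
                fixed.append(int(m))
        tables = compute_tables(data)
        cov = estimate_cov(tables, data)
    _check_nondegenerate(cov.variances, data.marker_names)
    auc_hat = estimate_auc(tables)
    N = data.n_subjects
    d = data.n_markers

    if config.method == "wb":
        res = wb_inference(data, tables, cov, config)
        res.boundary_fixed = tuple(fixed)
        return res

    if config.method in ("unadjusted", "bonferroni", "mcp"):
        stats = test_statistics(auc_hat, cov.variances, config.auc0, N)
        if config.method == "unadjusted":
            z = float(norm.ppf(1 - config.alpha))
            lower = ci_unadjusted(auc_hat, cov.variances, N, config.alpha)
        elif config.method == "bonferroni":
            z = float(norm.ppf(1 - config.alpha / d))
            lower = ci_bonferroni(auc_hat, cov.variances, N, config.alpha)
        else:
            z = equicoordinate_quantile(cov.R_hat, config.alpha, config.quantile_points)
            lower = ci_mcp(auc_hat, cov.variances, cov.R_hat, N, config.alpha, z=z)
        pvals = adjusted_p_values(
            config.method, stats, cov.R_hat, d, config.quantile_points
        )
    else:  # logit
        stats, s_diag = logit_statistics(auc_hat, cov.variances, config.auc0, N)
        z = equicoordinate_quantile(cov.R_hat, config.alpha, config.quantile_points)
        lower = ci_logit(auc_hat, s_diag, cov.R_hat, N, config.alpha, z=z)
        pvals = adjusted_p_values("logit", stats, cov.R_hat, d, config.quantile_points)

    return select_markers(
        auc_hat,
        stats,
        z,
        lower,
        pvals,
        config,
        data.marker_names,
        cov=cov,
        boundary_fixed=tuple(fixed),
    )
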