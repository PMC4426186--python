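"""Monte-Carlo engine: data generators and the FWER/power study.

Scenarios follow the design of a paired diagnostic screening trial:
multivariate normal (optionally exponentiated to log-normal, or discretised
to a 5-point ordinal scale) marker vectors for controls and cases, with the
case mean shifted marker-wise so that each marker's true AUC hits a target
value.  For normal data the binormal identity
``AUC = Phi(delta / sqrt(sigma0^2 + sigma1^2))`` gives the shift in closed
form; monotone transformations (log-normal) preserve the AUC exactly, and
the ordinal shift is calibrated by root search on the discretised AUC.

The least-favourable null configuration sets every true AUC equal to the
threshold ``auc0``; the empirical familywise error rate is the fraction of
replications in which any marker is (falsely) selected.  Power scenarios set
the true AUCs above the threshold and report the global rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .data import BiomarkerData
from .inference import logit_statistics, test_statistics
from .mvnorm import equicoordinate_quantile
from .ranks import compute_tables, estimate_auc, estimate_cov

__all__ = [
    "SimulationScenario",
    "StudyResult",
    "build_covariance",
    "generate_dataset",
    "run_study",
    "make_icm_like_fixture",
    "ordinal_auc",
    "calibrate_ordinal_shift",
]

FAMILIES = ("normal", "lognormal", "ordinal5")
COV_STRUCTURES = (
    "compound_symmetry",
    "unstructured",
    "hetero_diagonal_positive_pairing",
    "hetero_diagonal_negative_pairing",
)
#: procedures the Monte-Carlo engine can evaluate; the ``_logit`` variants
#: apply the plain normal / Bonferroni quantiles to logit-scale statistics
SIM_METHODS = (
    "unadjusted",
    "bonferroni",
    "unadjusted_logit",
    "bonferroni_logit",
    "mcp",
    "logit",
    "wb",
)
#: shared 5-category cut points on the control latent scale
ORDINAL_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)
_UNSTRUCTURED_SEED = 20150501  # fixed so the "unstructured" matrix is a named constant


@dataclass(frozen=True)
class SimulationScenario:
    """One Monte-Carlo cell.

    ``ccr`` is the case:control ratio written "1:k"; with total size N the
    cases form the smaller group, n1 = round(N/(k+1)), n0 = N - n1.
    ``true_auc`` may be a scalar (all markers equal) or a length-d vector.
    ``methods`` lists the procedures evaluated on the same replications.
    """

    family: str = "normal"
    cov_structure: str = "compound_symmetry"
    rho: float = 0.9
    d: int = 5
    N: int = 100
    ccr: str = "1:1"
    true_auc: float | tuple = 0.5
    auc0: float = 0.5
    methods: tuple = ("wb",)
    weights: str = "normal"
    nboot: int = 5000
    nsim: int = 5000
    alpha: float = 0.025
    seed: int = 0
    quantile_points: int = 1 << 12
    ordinal_calibration: str = "latent"
    scenario_id: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.cov_structure not in COV_STRUCTURES:
            raise ValueError(f"unknown covariance structure {self.cov_structure!r}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        methods = (self.methods,) if isinstance(self.methods, str) else tuple(self.methods)
        object.__setattr__(self, "methods", methods)
        for m in methods:
            if m not in SIM_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {SIM_METHODS}")
        n0, n1 = self.group_sizes()
        if n0 < 2 or n1 < 2:
            raise ValueError(f"ccr {self.ccr!r} with N={self.N} leaves a group below 2")
        if self.ordinal_calibration not in ("latent", "discretised"):
            raise ValueError("ordinal_calibration must be 'latent' or 'discretised'")
        auc = self.auc_vector()
        if np.any((auc <= 0) | (auc >= 1)):
            raise ValueError("true AUCs must lie strictly inside (0, 1)")

    def group_sizes(self) -> tuple[int, int]:
        parts = str(self.ccr).split(":")
        if len(parts) != 2 or int(parts[0]) != 1:
            raise ValueError(f"ccr must look like '1:k', got {self.ccr!r}")
        k = int(parts[1])
        n1 = int(round(self.N / (k + 1)))
        return self.N - n1, n1

    def auc_vector(self) -> np.ndarray:
        auc = np.asarray(self.true_auc, dtype=float)
        if auc.ndim == 0:
            auc = np.full(self.d, float(auc))
        if auc.shape != (self.d,):
            raise ValueError("true_auc must be scalar or length-d")
        return auc

    @property
    def is_null(self) -> bool:
        return bool(np.all(self.auc_vector() == self.auc0))


@dataclass(frozen=True)
class StudyResult:
    """Empirical rejection rate of one method in one scenario cell."""

    scenario: SimulationScenario
    method: str
    rate: float
    mc_se: float
    per_marker_rates: np.ndarray
    nsim: int

    @property
    def is_type_i_error(self) -> bool:
        return self.scenario.is_null


def _unstructured_correlation(d: int) -> np.ndarray:
    """Fixed, reproducible random correlation matrix with spread eigenvalues."""
    rng = np.random.default_rng(_UNSTRUCTURED_SEED)
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    lam = np.linspace(0.2, 2.0, d)
    lam *= d / lam.sum()
    S = (Q * lam) @ Q.T
    scale = 1.0 / np.sqrt(np.diag(S))
    R = S * np.outer(scale, scale)
    np.fill_diagonal(R, 1.0)
    return R


#: marker-wise variance profile of the heteroscedastic structures
def _hetero_variances(d: int) -> np.ndarray:
    return np.linspace(1.0, 3.0, d)


def build_covariance(structure: str, rho: float, d: int, group: str = "larger") -> np.ndarray:
    """Group covariance matrix for one scenario.

    ``group`` is "larger" or "smaller" (by sample size).  Compound symmetry
    and the unstructured matrix are shared by both groups (unit variances);
    the heteroscedastic structures are diagonal with variances increasing
    across markers, assigned to the larger group under positive pairing and
    to the smaller group under negative pairing (the other group keeps unit
    variances).
    """
    if structure not in COV_STRUCTURES:
        raise ValueError(f"unknown covariance structure {structure!r}")
    if group not in ("larger", "smaller"):
        raise ValueError("group must be 'larger' or 'smaller'")
    if structure == "compound_symmetry":
        if not 0 <= rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        R = np.full((d, d), float(rho))
        np.fill_diagonal(R, 1.0)
        return R
    if structure == "unstructured":
        return _unstructured_correlation(d)
    heavier = "larger" if structure.endswith("positive_pairing") else "smaller"
    v = _hetero_variances(d) if group == heavier else np.ones(d)
    return np.diag(v)


def ordinal_auc(delta: float, sigma0: float = 1.0, sigma1: float = 1.0,
                thresholds=ORDINAL_THRESHOLDS) -> float:
    """AUC of the 5-point discretisation of N(0, s0^2) vs N(delta, s1^2)."""
    t = np.asarray(thresholds, dtype=float)
    c0 = np.concatenate([[0.0], norm.cdf(t / sigma0), [1.0]])
    c1 = np.concatenate([[0.0], norm.cdf((t - delta) / sigma1), [1.0]])
    p0 = np.diff(c0)
    p1 = np.diff(c1)
    # midrank kernel: P(X0 < X1) + 0.5 P(X0 = X1) over the 5 categories
    return float(np.sum(p1 * (c0[:-1] + 0.5 * p0)))


def calibrate_ordinal_shift(target_auc: float, sigma0: float = 1.0, sigma1: float = 1.0,
                            thresholds=ORDINAL_THRESHOLDS, tol: float = 1e-6) -> float:
    """Latent shift whose discretised AUC equals ``target_auc`` (root search)."""
    t = np.asarray(thresholds, dtype=float)
    p_top = 1 - norm.cdf(t[-1] / sigma0)
    p_bot = norm.cdf(t[0] / sigma0)
    max_auc = 1 - 0.5 * p_top  # all cases in the top category
    min_auc = 0.5 * p_bot
    if not min_auc + tol < target_auc < max_auc - tol:
        raise ValueError(
            f"target AUC {target_auc} unreachable after discretisation "
            f"(attainable range ({min_auc:.4f}, {max_auc:.4f}))"
        )
    lo, hi = -50.0, 50.0
    return float(brentq(lambda dd: ordinal_auc(dd, sigma0, sigma1, thresholds) - target_auc,
                        lo, hi, xtol=tol))


def generate_dataset(scenario: SimulationScenario, rng: np.random.Generator) -> BiomarkerData:
    """One synthetic dataset with the scenario's marginal AUCs.

    Controls are centred d-variate normal with the scenario covariance;
    cases are shifted marker-wise by the binormal (or calibrated ordinal)
    amount.  Log-normal data exponentiates the same normal draws, leaving
    every rank statistic unchanged.
    """
    n0, n1 = scenario.group_sizes()
    d = scenario.d
    role0 = "larger" if n0 >= n1 else "smaller"
    role1 = "smaller" if role0 == "larger" else "larger"
    S0 = build_covariance(scenario.cov_structure, scenario.rho, d, role0)
    S1 = build_covariance(scenario.cov_structure, scenario.rho, d, role1)
    sd0, sd1 = np.sqrt(np.diag(S0)), np.sqrt(np.diag(S1))
    auc = scenario.auc_vector()
    if scenario.family == "ordinal5" and scenario.ordinal_calibration == "discretised":
        # shift chosen so the AUC *after* discretisation hits the target
        delta = np.array(
            [calibrate_ordinal_shift(a, s0, s1) for a, s0, s1 in zip(auc, sd0, sd1)]
        )
    else:
        # binormal identity; for ordinal data under the default "latent"
        # calibration the discretisation then attenuates the effective AUC
        # toward 1/2, as for any real grading scale read off a latent trait
        delta = norm.ppf(auc) * np.sqrt(sd0**2 + sd1**2)
    L0 = np.linalg.cholesky(S0)
    L1 = np.linalg.cholesky(S1)
    X0 = rng.standard_normal((n0, d)) @ L0.T
    X1 = rng.standard_normal((n1, d)) @ L1.T + delta
    if scenario.family == "lognormal":
        X0, X1 = np.exp(X0), np.exp(X1)
    elif scenario.family == "ordinal5":
        t = np.asarray(ORDINAL_THRESHOLDS)
        X0 = np.digitize(X0, t).astype(float) + 1.0
        X1 = np.digitize(X1, t).astype(float) + 1.0
    values = np.vstack([X0, X1])
    status = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return BiomarkerData(values, status)


def _child_rng(master_seed: int, rep: int) -> np.random.Generator:
    # child streams depend only on (master seed, index): changing nsim never
    # alters earlier replications
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(rep))))


def run_study(scenario: SimulationScenario, progress=None) -> dict[str, StudyResult]:
    """Empirical FWER (null cells) or power (alternative cells) per method.

    All requested methods are evaluated on the same replications, sharing
    the rank tables, covariance estimate and (for mcp/logit) the
    equicoordinate quantile.  Boundary-degenerate markers, which can occur
    at high AUC with small groups, receive the conservative boundary fix
    automatically.
    """
    from .wild_bootstrap import WeightScheme, _draw_max_stats, empirical_quantile

    methods = scenario.methods
    d, N = scenario.d, scenario.N
    alpha = scenario.alpha
    need_raw = any(m in ("unadjusted", "bonferroni", "mcp") for m in methods)
    need_logit = any(
        m in ("unadjusted_logit", "bonferroni_logit", "logit", "wb") for m in methods
    )
    need_quantile = any(m in ("mcp", "logit") for m in methods)
    z_unadj = norm.ppf(1 - alpha)
    z_bonf = norm.ppf(1 - alpha / d)
    rejections = {m: np.zeros((scenario.nsim, d), dtype=bool) for m in methods}

    for rep in range(scenario.nsim):
        rng = _child_rng(scenario.seed, rep)
        data = generate_dataset(scenario, rng)
        tables = compute_tables(data)
        cov = estimate_cov(tables, data)
        if cov.degenerate.any():
            from .inference import apply_boundary_fix

            auc = estimate_auc(tables)
            for m_idx in np.flatnonzero(cov.degenerate):
                if auc[m_idx] in (0.0, 1.0):
                    data = apply_boundary_fix(data, int(m_idx))
            tables = compute_tables(data)
            cov = estimate_cov(tables, data)
        auc_hat = estimate_auc(tables)
        if need_raw:
            t_raw = test_statistics(auc_hat, cov.variances, scenario.auc0, N)
        if need_logit:
            t_log, _ = logit_statistics(auc_hat, cov.variances, scenario.auc0, N)
        if need_quantile:
            z_mcp = equicoordinate_quantile(cov.R_hat, alpha, scenario.quantile_points)
        for m in methods:
            if m == "unadjusted":
                rejections[m][rep] = t_raw >= z_unadj
            elif m == "bonferroni":
                rejections[m][rep] = t_raw >= z_bonf
            elif m == "unadjusted_logit":
                rejections[m][rep] = t_log >= z_unadj
            elif m == "bonferroni_logit":
                rejections[m][rep] = t_log >= z_bonf
            elif m == "mcp":
                rejections[m][rep] = t_raw >= z_mcp
            elif m == "logit":
                rejections[m][rep] = t_log >= z_mcp
            else:  # wild bootstrap
                scheme = WeightScheme(scenario.weights)
                A = _draw_max_stats(tables, scenario.nboot, scheme, rng)
                z_star = empirical_quantile(A, alpha)
                rejections[m][rep] = t_log >= z_star
        if progress is not None and (rep + 1) % 100 == 0:
            progress(rep + 1, scenario.nsim)

    out = {}
    for m in methods:
        rej = rejections[m]
        global_rate = float(rej.any(axis=1).mean())
        se = float(np.sqrt(global_rate * (1 - global_rate) / scenario.nsim))
        out[m] = StudyResult(
            scenario=replace(scenario, methods=(m,)),
            method=m,
            rate=global_rate,
            mc_se=se,
            per_marker_rates=rej.mean(axis=0),
            nsim=scenario.nsim,
        )
    return out


def make_icm_like_fixture(seed: int = 2015) -> BiomarkerData:
    """Synthetic stand-in emulating the shape of a small real screening trial.

    67 subjects (26 cases, 41 controls), four strongly correlated markers
    with high accuracies, the fourth separating the groups perfectly
    (estimated AUC exactly 1) so the boundary-fix path can be exercised.
    The real trial's data are not public; this fixture only mimics its
    dimensions and qualitative features.
    """
    rng = np.random.default_rng(seed)
    scen = SimulationScenario(
        family="normal", cov_structure="compound_symmetry", rho=0.8,
        d=4, N=67, ccr="1:1", true_auc=(0.85, 0.90, 0.93, 0.97),
        auc0=0.8, nsim=1, seed=seed,
    )
    # 67 with "1:1" would split 34/33; build the 41/26 split directly
    n0, n1 = 41, 26
    S = build_covariance("compound_symmetry", 0.8, 4)
    L = np.linalg.cholesky(S)
    delta = norm.ppf(scen.auc_vector()) * np.sqrt(2.0)
    X0 = rng.standard_normal((n0, 4)) @ L.T
    X1 = rng.standard_normal((n1, 4)) @ L.T + delta
    # force complete separation on the last marker
    X1[:, 3] += X0[:, 3].max() - X1[:, 3].min() + 0.5
    values = np.vstack([X0, X1])
    status = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return BiomarkerData(
        values, status, ("dI_carb", "dI_cAMP", "dI_hista", "dI_sum")
    )
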