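# Methods

## Model

Measurements form i.i.d. subject vectors `X_s = (X_s(1), ..., X_s(d))` with a
binary gold-standard status (control `i=0`, case `i=1`; group sizes `n0`,
`n1`, `N = n0 + n1`). All marginal distributions are arbitrary apart from
excluding markers that are one-point distributions in *both* groups; to treat
continuous, discrete and ordinal data uniformly, distribution functions are
taken in their normalised (mid) version, which is exactly the midrank
convention for ties. The estimand per marker is the ordinal effect

    AUC(l) = P(X0(l) < X1(l)) + 0.5 P(X0(l) = X1(l)),

and the hypotheses are one-sided non-inferiority screens
`H0(l): AUC(l) <= AUC0` tested jointly with strong FWER control at
`alpha = 0.025` one-sided (the regulatory one-sided 97.5% CI convention).

## Estimation

`AUC_hat(l)` is the midrank estimator `(R1_bar - R0_bar)/N + 1/2`. The
covariance of `sqrt(N)(AUC_hat - AUC)` is estimated from normed placements
`Z_s = (pooled midrank - within-group midrank) / (opposite group size)`:

    V_hat = N * (V0/n0 + V1/n1),   Vi = sample covariance of group-i placements.

For `d = 1` this is the classical two-components (DeLong-type) variance; the
implementation is verified in the test suite against a brute-force pairwise
kernel (estimator) and cross-checked during development against an
independent DeLong implementation (agreement to 7 significant digits).
Placements are computed by the rank-difference identity, O(N log N) per
marker; ties are handled only through midranks — no jittering.

Degenerate markers (`AUC_hat` exactly 0 or 1) have zero estimated variance.
Policy: `error` (default) names the marker and suggests the fix;
`boundary_fix` replaces the largest control measurement by the smallest case
measurement (mirrored at 0), which decreases the effect and increases the
variance, i.e. is conservative, and is reported in the results object.

## Simultaneous procedures

With `T(l) = (AUC_hat(l) - AUC0) sqrt(N / v_hat(l,l))` and the estimated
correlation matrix `R_hat` of the statistics:

* unadjusted: reject if `T(l) >= z_{1-alpha}`;
* Bonferroni: `z_{1-alpha/d}`;
* MCP: `z_{1-alpha,1}(R_hat)`, the one-sided equicoordinate quantile of
  `N(0, R_hat)`;
* Logit: same quantile applied to
  `T~(l) = (logit(AUC_hat) - logit(AUC0)) sqrt(N / s_hat(l,l))`,
  `s_hat = v_hat / (AUC_hat (1 - AUC_hat))^2` (delta method);
* Wild bootstrap: `T~(l)` compared against the empirical `(1-alpha)`
  quantile `z*` of `nboot` max statistics `A*_j = max_l T*(l)`, where
  `T*(l) = (Z1_bar* - Z0_bar*) / sqrt(v0*/n0 + v1*/n1)` is built from
  weighted centred placements `Z*_s = W_s (Z_s - Z_bar_group)`.

Lower confidence bounds follow by pivot inversion (raw scale for
unadjusted/Bonferroni/MCP, clipped at 0 — an AUC below 0 is meaningless and
clipping cannot alter a decision since `AUC0 > 0`; expit-transformed logit
scale for Logit/WB). Decisions from statistics, bounds, and adjusted
p-values coincide by construction; the results object verifies this.

Adjusted p-values: `1 - Phi(T)` (unadjusted), `min(1, d(1 - Phi(T)))`
(Bonferroni), `1 - P(all components of N(0, R_hat) <= t)` (MCP/Logit), and
for the wild bootstrap `1 - (1/nboot) sum_j I{T~(l) >= A*_j}` — one minus
the retention proportion, so small p means strong evidence.

### Numerical choices

* Equicoordinate probabilities use the Genz sequential-conditioning
  algorithm on a scrambled Sobol point set with a fixed seed: deterministic
  across runs, absolute error ~1e-6 at the default 2^14 points (~1e-5 at
  the 2^12 points used inside simulations, where it is dominated by
  Monte-Carlo noise). The quantile is found by Brent search on the bracket
  `[z_{1-alpha}, z_{1-alpha/d}]`, which provably contains it.
* Comonotone blocks of `R_hat` (duplicate markers) are collapsed to one
  representative before factorisation; other rank deficiencies get a 1e-9
  diagonal jitter. Non-symmetric matrices or diagonals differing from 1 are
  hard errors.
* The bootstrap statistic is standardised as written above: the group
  variances of the weighted placements already estimate
  `Var(Z1_bar* - Z0_bar*)`, so no extra `sqrt(N)` factor appears, and the
  variance pairing is `v0*/n0 + v1*/n1`, matching the pairing inside
  `V_hat`. A `denominator="as_printed"` switch exposes the cross-paired
  variant `v1*/n0 + v0*/n1` for comparison; at a 1:1 case-control ratio the
  two coincide.
* Empirical quantile: the `ceil((1-alpha) nboot)`-th order statistic
  (higher interpolation), so the test never rejects more often than the
  interval implies at finite `nboot`; ties between `T~` and `A*` count as
  retention. Finite `nboot` measurably inflates rejection rates (about
  +0.6pp at `nboot = 800` versus 2500 at the standard scenario), so
  study-grade runs should use `nboot >= 2000`; the analysis default is
  10,000.
* Weight schemes: Rademacher, standard normal (default, the recommended
  scheme), uniform on `[-sqrt(12)/2, sqrt(12)/2]`. One RNG stream per
  analysis; each draw's `N` weights are consecutive stream values in
  subject order (controls first). Identical (data, seed, nboot, scheme)
  give bit-identical results. Draws in which some marker's bootstrap
  variance vanishes are redrawn (cap 100 rounds, then a hard error).
* The Efron comparison procedure resamples subjects within groups,
  studentises the logit-scale statistic centred at the original estimates,
  and uses the empirical max-quantile. Degenerate resamples are redrawn
  with the same cap; data sets where almost all resamples are degenerate
  (all markers separating) make it fail loudly — one facet of why
  case-resampling is not recommended here.

## Synthetic-data generator

The Monte-Carlo engine emulates a paired screening study:

* Controls are centred `d`-variate normal with covariance from one of:
  compound symmetry (`rho` on the off-diagonal; standard scenario
  `rho = 0.9`), a fixed seeded "unstructured" correlation matrix
  (eigenvalues spread linearly 0.2–2, rotated by a seeded orthogonal
  matrix — a named constant so results are reproducible), or diagonal
  heteroscedastic matrices with marker variances 1–3, assigned to the
  larger group (positive pairing) or the smaller group (negative pairing).
* Cases are shifted marker-wise by the binormal identity
  `delta = Phi^{-1}(AUC) sqrt(sigma0^2 + sigma1^2)`.
* Log-normal data exponentiates the same draws — every rank statistic is
  unchanged, which the tests assert.
* Ordinal data discretises both groups on the shared fixed grid
  `{-1.5, -0.5, 0.5, 1.5}` of the control scale into 5 categories.
  Two calibration modes exist. The default, `latent`, gives the *latent*
  normal the target AUC and then discretises; the discretisation attenuates
  the effective ordinal AUC towards 1/2 (at a latent 0.9 the ordinal AUC is
  0.875), which is how a real grading scale read off a latent trait
  behaves, and makes a threshold test at the latent value conservative —
  increasingly so at higher accuracy, nominal at 0.5. The alternative,
  `discretised`, root-solves the shift so the *post-discretisation* AUC
  hits the target exactly (tolerance 1e-6; unreachable targets — the grid
  caps the ordinal AUC at 0.967 — raise an error). The default was chosen
  because it reproduces the qualitative operating characteristics a 5-point
  scale shows in practice; the calibrated mode is the right tool when the
  ordinal AUC itself is the design quantity.
* Case:control ratio "1:k" with total `N`: `n1 = round(N/(k+1))` cases (the
  smaller group), `n0 = N - n1`.
* Replication `r` uses a child generator seeded by `(master seed, r)`, so
  enlarging `nsim` never changes earlier replications; within a
  replication, bootstrap weights continue the same stream.
* FWER cells set every true AUC to `AUC0` (least favourable null); power is
  the global rejection rate (any marker selected), with per-marker rates
  also reported. Degenerate markers arising at high AUC with small groups
  receive the boundary fix automatically.

The simulation engine also offers `unadjusted_logit` / `bonferroni_logit`,
the plain normal and Bonferroni quantiles applied to the logit-scale
statistics: for a single-AUC analysis practitioners typically use the
logit-based marginal interval, and on the raw scale these two comparators are
themselves strongly liberal at high accuracy (Bonferroni ~8.5% at
AUC0 = 0.9), which would say more about the raw-scale statistic than about
multiplicity handling.

What the generator does *not* emulate: real marker panels with heterogeneous
marginal shapes and tie structures, missing data, covariate-dependent
accuracy, or verification bias. Passing operating-characteristic tests shows
the procedures behave as designed under these stylised conditions, not that
any particular real panel meets them. The bundled
`make_icm_like_fixture` is a synthetic stand-in that only mimics the
dimensions of a small real screening trial (67 subjects 41/26, four strongly
correlated markers, one separating perfectly); it carries no real
measurements.

## Problem sizes

Unit and property tests run at small `n` with brute-force oracles. The
operating-characteristic tests and `scripts/acceptance.py` use roughly 1000
simulation runs per cell with 1000–2500 bootstrap draws (500 x 2000 for the
nine N-by-d cells), chosen so each empirical rate carries a Monte-Carlo
standard error of about half a percentage point while the whole run stays in
the minutes range on a single CPU; tolerances are
`3 sqrt(p(1-p)/nsim)` plus 0.3 percentage points for the reduced bootstrap
size. A cluster-scale rerun would use 5000 x 5000.

## Known limitations

* The untransformed MCP is reliable only at moderate accuracies; at
  `AUC0 = 0.9`, `N = 100` it is strongly liberal (~9.5% empirical FWER at
  nominal 2.5% under these study conditions) and is retained mainly as the
  basis for its logit and bootstrap refinements.
* The wild bootstrap inherits mild liberality at extreme case-control
  imbalance (1:9) — use the logit procedure's conservatism as a guard there.
* p-values are single-step adjusted; no step-down refinement is offered
  (compatibility with the reported simultaneous bounds would be lost).
* Two-sided simultaneous intervals are out of scope; the construction is
  one-sided throughout.
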