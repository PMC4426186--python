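# aucselect

Nonparametric simultaneous AUC inference for selecting diagnostic biomarkers
in early diagnostic trials.

## The problem

In a biomarker screening study, `d` candidate diagnostic tests are measured
on the *same* `N` subjects, whose true disease state (case/control) is fixed
by a gold standard. Because no cut-off has been chosen yet, each marker's
accuracy is summarised by the area under its ROC curve,

    AUC = P(X_control < X_case) + 0.5 * P(X_control = X_case),

which is free of cut-offs and invariant under monotone rescaling, so it works
for continuous, discrete and ordered-categorical measurements alike. A marker
is *selected* when its AUC demonstrably exceeds a pre-specified
non-inferiority threshold `AUC0`; with several markers tested at once, the
familywise error rate (FWER) must be controlled, and the strong correlation
between markers measured on the same subjects should be exploited rather than
ignored.

## The method

Everything is rank-based. Per marker, the AUC is estimated from midranks,

    AUC_hat = (R1_bar - R0_bar)/N + 1/2,

and the joint covariance of the estimators is estimated from *placements*
(the empirical opposite-group distribution evaluated at each observation,
computed as pooled minus within-group midranks) — the multivariate analogue
of the DeLong variance components. Four simultaneous one-sided procedures
screen the markers against `AUC0`, all single-step and compatible (the test
decision and the confidence-bound decision always coincide):

* **bonferroni** — normal quantile `z_{1-alpha/d}`;
* **mcp** — multiple contrast test: the equicoordinate `(1-alpha)` quantile
  of a centred multivariate normal with the *estimated* correlation matrix
  of the statistics, on the raw AUC scale;
* **logit** — the same quantile applied to logit-transformed estimates
  (delta method), which converges much faster for accuracies near 1;
* **wb** (default) — a **wild bootstrap**: the centred placements of every
  subject are multiplied by i.i.d. mean-0/variance-1 weights (Rademacher,
  standard normal, or uniform), the studentised contrast is recomputed per
  marker, and the empirical `(1-alpha)` quantile of the max statistic over
  `nboot` draws replaces the asymptotic quantile. This reproduces the joint
  law of the statistics conditionally on the data — under null and
  alternative alike — and is the recommended procedure for small samples and
  high accuracies.

An unadjusted variant (local level = global level) and a conventional
case-resampling (Efron) bootstrap are included for comparison; both fail to
control the FWER and exist to demonstrate why the adjusted procedures are
needed.

Markers that separate the groups perfectly (`AUC_hat = 1`) have a zero
variance estimate; the package's `boundary_fix` policy applies the
conservative tie-creating modification (the largest control measurement is
replaced by the smallest case measurement) and reports having done so.

## Worked example

```python
import numpy as np
from aucselect import AUCNonInferiority, make_icm_like_fixture

data = make_icm_like_fixture(seed=2015)   # 41 controls, 26 cases, 4 markers
model = AUCNonInferiority(data, auc0=0.8) # one-sided alpha = 0.025
res = model.fit(method="wb", boundary_policy="boundary_fix", seed=1)
print(res.summary())
```

prints

```
Simultaneous one-sided AUC inference (wb)
  H0: AUC <= 0.8   alpha = 0.025 (one-sided)
  critical value: 2.2805   [wild bootstrap, normal weights, nboot=10000]
  boundary fix applied to: dI_sum

  marker    auc  lower_bound  p_adj  statistic  selected
 dI_carb 0.8086       0.6425 0.7466     0.1463     False
 dI_cAMP 0.8583       0.7090 0.3997     1.0394     False
dI_hista 0.9493       0.8454 0.0045     2.8602      True
  dI_sum 0.9995       0.9883 0.0000     4.4372      True

global H0 rejected: True (2 of 4 markers selected)
```

Reading: `auc` is the midrank estimate; `lower_bound` is the one-sided
simultaneous 97.5% lower confidence limit (here wild-bootstrap, logit scale);
a marker is selected exactly when that bound exceeds 0.8, equivalently when
its statistic reaches the bootstrap critical value, equivalently when its
adjusted p-value is below 0.025. The perfectly separating marker `dI_sum`
was made analysable by the conservative boundary fix (its estimate drops to
0.9995 and its variance grows).

The same analysis runs from the shell on any CSV with a status column:

```sh
aucselect analyze --input markers.csv --status-col disease \
    --control-label no --case-label yes --auc0 0.8 --seed 1 --boundary-fix
aucselect simulate --scenarios scenarios.yaml --output results.tsv
```

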