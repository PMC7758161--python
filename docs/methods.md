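# Methods

## The biological question and the model

CD57 is widely used as a surface marker of replicative senescence in
memory T cells, yet CD57+ memory T cells accumulate with age. Two
non-exclusive mechanisms could sustain the CD57+ pool: phenotypic
conversion of dividing CD57- memory cells, and self-renewal by division
within the CD57+ pool itself. `memokin` implements the quantitative
machinery to distinguish them from in vivo heavy-water labeling plus
single-molecule telomere-length (STELA) data.

### Population and label kinetics

Two linked compartments, CD57- (x1, source) and CD57+ (x2, target):

    dx1/dt = p1 x1 - z1 x1
    dx2/dt = p2 x2 - z2 x2 + m x1

with proliferation rates p, disappearance rates z, and conversion rate m
(all per day). Conversion is assumed coincident with division, so label
flows into the CD57+ pool both through its own division (p2) and through
conversion of dividing CD57- cells. With U(t) the fraction of deuterium
in body water and b_w the amplification from body water to DNA
deoxyribose, the labeled-deoxyadenosine fractions obey

    dL1/dt = p1 b_w U(t)        - z1* L1
    dL2/dt = (p2 + mR) b_w U(t) - z2* L2,      L1(0) = L2(0) = 0,

where R = x1/x2 is the pool-size ratio and z* are the loss rates of
*labeled* cells (kinetic heterogeneity allows z* to differ from the
population z). Only the composite mR is identifiable from label data,
and — crucially — L2 constrains only the *sum* p2 + mR. An alternative
variant in which conversion is not coupled to division
(dL2/dt = p2 b_w U - z2* L2 + mR (L1 - L2)) is exposed behind a flag;
it is an interpretation, since only its rejection is on record.

### Body-water forcing

U(t) is empirical: U(t) = f (1 - e^(-delta t)) + beta e^(-delta t) during
labeling (t <= tau) and exponential washout U(tau) e^(-delta (t - tau))
afterwards — the only continuous choice consistent with the rise-and-fall
profile of saliva enrichment. tau is fixed by design (49 days); f, beta,
delta are fitted per volunteer from saliva by bounded least squares with
a deterministic multistart. The washout branch is a documented
interpretation: the source material prints the labeling expression for
both phases, which cannot be literal.

### Telomere dynamics

Mean division indices mu (divisions accrued per cell) follow

    dmu1/dt = 2 p1
    dmu2/dt = 2 p2 - mR (mu2 - mu1 - K)

with K the divisions' worth of telomere erosion incurred at conversion
(default 0, telomerase being highly active during clonal expansion). The
gap mu2 - mu1 relaxes at rate mR to 2 (p2 - p1)/mR + K, so at steady
state the telomere-length difference (CD57- minus CD57+ mean, in bp) is

    Delta_C = epsilon (2 (p2 - p1)/mR + K),

epsilon = 50 bp lost per division by default. Delta_C breaks the p2/mR
degeneracy left by the label data: that is the entire reason the telomere
observation enters the fit. Delta_C diverges as mR -> 0 with p1 != p2;
inside the fit mR is floored at 1e-6/day and results that sit at the
floor are flagged non-equilibrium rather than silently reported.

## Joint fitting

Per volunteer-lineage the free parameters are p1, z1*, p2, z2*, mR
(4 when p2 is fixed to 0). Fitting is two-stage: U(t) first from saliva,
then the joint fit with U fixed. The joint residual vector concatenates

* label residuals for both subsets, each divided by the mean observed
  label enrichment of that volunteer-lineage and by the number of label
  points (16 under the default design), and
* the telomere residual (Delta_C - Delta_obs) divided by |Delta_obs|,
  floored at epsilon bp to keep a near-zero observed difference from
  exploding the weight.

This mean-normalisation makes the single telomere observation weigh
against the ~16 label points. The normaliser grouping (per data type,
per volunteer-lineage) is a design choice: it is the reading that makes
the two data types contribute comparably.

The optimizer is a seeded pseudo-random global search — 2000 uniform
draws inside the bounds, evaluated in a vectorised pass through the
closed-form label solution — followed by bounded least-squares refinement
(`scipy.optimize.least_squares`) of the best three draws. Refinement is
a trf/dogbox hybrid: trust-region-reflective first (capped at 200
evaluations), continued by dogbox from trf's endpoint if trf stalls.
The two methods fail on complementary geometries here — the constrained
(p2 = 0) fit typically ends on the boundary of the parameter space (it
drives p1 toward 0 to salvage the telomere residual), where trf crawls,
while dogbox zigzags on smooth interior optima — and full convergence
matters: under-optimized fits visibly distort the nested F test.
Identical seeds give bit-identical fits. Bounds default to [0, 0.2]/day for the four
rates and [0, 0.4]/day for mR (the conversion bound is quoted as [0, 40]
without a printed unit; it is read as % per day). For nested comparisons
`fit_nested_pair` additionally seeds the full fit from the constrained
optimum, enforcing RSS_full <= RSS_constrained as nesting requires.

### Standard errors

Point estimates come from the weighted least squares above. For their
uncertainty two asymptotic covariance estimators are provided:

* `pooled` — s^2 (J'J)^{-1} with s^2 = RSS/(n - k), J the
  finite-difference Jacobian of the weighted residuals. Valid only if all
  weighted residuals share one error variance.
* `robust` (default) — the sandwich (J'J)^{-1} J' Sigma J (J'J)^{-1},
  with the label-noise variance estimated from the label residuals and
  the variance of the observed telomere difference computed directly from
  the per-molecule STELA spread (s1^2/n1 + s2^2/n2).

The robust form exists because the joint weighting is deliberately
heteroscedastic: the weighted telomere residual is ~10^3 times noisier
than a weighted label residual, yet the p2/mR split can zero it exactly
at the optimum, so the pooled form never sees the telomere noise and
understates Var(p2) badly (measured 95% Wald coverage ~0.4 instead of
~0.95). With the robust form, coverage of p2 in the simulation study is
~0.95. When only subset means (no molecules) are available the robust
form falls back to pooled.

`n` for the F test and AICc counts all fitted observations: label points
of both subsets plus the telomere difference (17 under the default
design). The n behind the original analysis is not on record, so this
count is configurable in spirit — it is documented here and derives
directly from the residual vector length.

### Model comparison and the self-renewal statistic

The p2 = 0 model is tested against the full model with
F = ((RSS0 - RSS1)/(k1 - k0)) / (RSS1/(n - k1)) referred to
F(k1 - k0, n - k1), and with the small-sample AIC,
AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1); Delta AICc =
AICc(constrained) - AICc(full). The headline statistic is the
self-renewal contribution 100 p2/(p2 + mR) — the percentage of newly
generated CD57+ cells arising from division within the CD57+ pool —
reported rounded to integers, with rates in % per day at two decimals.

Because p2 >= 0 puts the null hypothesis on the parameter boundary, the
F test's null p-values are *not* uniform: about 10% of null replicates
end with the full fit pinned at p2 = 0, giving F = 0 and an atom at
p = 1 (a chi-bar-square phenomenon). The lower range is close to
uniform, so the simulation suite checks validity — rejection frequency
at or below nominal at every level — rather than uniformity; the
realised level at alpha = 0.05 is about 0.03-0.05.

## The synthetic-data generator

`simulate` emulates the 7-week labeling study design: label sampling at
weeks 1, 3, 5, 7 (labeling) and 8, 10, 14, 18 (washout); saliva weekly
through week 7 and at the washout visits; one telomere observation per
volunteer-lineage built from per-molecule draws. Defaults:

| quantity | default | rationale |
| --- | --- | --- |
| true rates | published per-lineage medians | the documented operating point |
| body-water curve | f = 0.015, delta = 0.06/day, beta = 0.005 | typical oral 2H2O protocol scale; no published values exist |
| saliva noise sd | 5e-4 (enrichment fraction) | visual scatter of published saliva fits |
| label noise sd | 5% of peak CD57- enrichment | visual scatter of published enrichment data |
| telomere molecules | 30 per subset, sd 2000 bp, 5 kb anchor | STELA per-molecule spread |

Noise is additive Gaussian truncated at zero; the error model of the real
measurements is nowhere stated, so these are artifact choices. The
generator reproduces exactly what the model assumes — no sort impurity,
no isotopomer chemistry, no telomere-distribution shape, R constant over
the study. Passing recovery tests therefore demonstrate identifiability
and correctness of the estimation machinery under the design, not
robustness to real-world measurement pathology.

`recovery_experiment` runs generate -> refit-body-water -> joint fit
(optionally plus the constrained fit and nested comparison) over seeded
replicates and aggregates bias, RMSE, Wald coverage, F p-values and
Delta AICc. The shipped simulation studies use 200 replicates for
coverage and null calibration and 100 for the model-selection direction;
these sizes give binomial standard errors of ~1.5-2 percentage points on
the checked frequencies.

## Numerical choices

* Label trajectories: exact piecewise-exponential solution with a
  cancellation-safe kernel ((e^{-yt} - e^{-xt})/(x - y) switches to a
  series when |x - y| t < 1e-7); cross-validated against LSODA
  integration split at the tau discontinuity (agreement < 1e-8).
* Population trajectories: matrix exponential of the (triangular) rate
  matrix — exact.
* Division indices: closed-form linear + exponential relaxation — exact.
* Degenerate inputs: all-zero saliva fits are flagged `degenerate`;
  n <= k designs and singular J'J report SEs as not-determined (NaN,
  rendered "N/D"); empty telomere subsets and negative enrichments are
  schema errors with line numbers; datasets without telomere data get a
  flagged label-only fit.
* Ties in the global search are broken by stable argsort on the draw
  index, preserving bit-reproducibility.

## Known limitations

* z and z* are treated as the same quantities when reporting (the
  published table heads its columns z1, z2 while fitting z1*, z2*); the
  population-level z is conceptually distinct and not separately
  identifiable here.
* The per-volunteer m and R are only reported separately when a measured
  R is supplied; otherwise everything stays in the composite mR.
* Wald intervals on a bounded parameter near 0 (mR, and p2 under the
  null) are approximate; profile or bootstrap intervals are out of scope.
* The granulocyte-based estimation of b_w is not implemented; b_w is a
  configuration constant (default 3.5).
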