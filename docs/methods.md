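# Methods

## Problem and data model

`beefdmi` predicts and validates daily dry matter intake (DMI, kg/d) of
confined beef cows from three descriptors: shrunk body weight (SBW, kg;
live weight × 0.96 when only live weight is reported), diet net energy
for maintenance concentration (NEm, Mcal/kg DM), and production stage
(STAGE, 0 = nonlactating, 1 = lactating), with milk yield (kg/d) as an
optional adjustment in two of the classical equations. The
observational unit throughout is the *treatment mean* — the per-diet,
per-group average of a feeding trial — not the individual animal.
Body condition score (1–9) is carried as data but is never a predictor.

## Prediction equations

Six previously published equations (A–C nonlactating, D–F lactating)
and two newer pooled-data models are implemented as closed forms:

| id | formula (DMI, kg/d) |
|---|---|
| A | SBW^0.75 · (0.0194 + 0.0545·NEm) |
| B | SBW^0.75 · (0.04997·NEm² + 0.04631) / NEm |
| C | (−0.0323·NEm² + 0.0944·NEm − 0.0418) · SBW |
| D | A + 0.2·milk |
| E | (SBW^0.75·(0.04997·NEm² + 0.04631) + 0.2·milk) / NEm |
| F | (−0.0261·NEm² + 0.07777·NEm − 0.0277) · SBW |
| NEMI_2022 | NEMI = 0.224·NEm + 0.0346·STAGE − 0.142; DMI = NEMI·SBW^0.75/NEm |
| DMI_2022 | 3.27·STAGE + 9.21·NEm + 0.133·SBW^0.75 − 14.38 |

Notes on fidelity and units:

* C and F scale with **full** SBW, not SBW^0.75 — implemented exactly as
  printed, no "correction". Their quadratics have interior vertices at
  1.461 and 1.490 Mcal/kg, which is why those two curves stabilize near
  1.4–1.5 Mcal/kg while A/B/D/E keep rising.
* The NEMI response is sometimes described on a kcal scale, but the
  coefficients above are dimensionally consistent only in Mcal per
  kg^0.75 per day (0.224·1.3 − 0.142 ≈ 0.15); the package uses Mcal
  throughout so that DMI = NEMI·SBW^0.75/NEm lands in kg/d.
* Diet NEm outside a configurable validity window (default
  0.7–2.1 Mcal/kg) warns rather than errors, because the response
  curves are legitimately drawn past the data range; only NEm ≤ 0 is an
  error.
* Exact algebraic identities hold by construction and are property-
  tested: D = A + 0.2·milk and E = B + 0.2·milk/NEm; the DMI_2022
  lactating-minus-nonlactating difference is 3.27 kg/d at every input
  (intercept shift only).

Two worked quantities deserve comment. For a 545-kg cow on a
1.3 Mcal/kg diet, the 3.27 kg/d lactation adjustment is 20.6% ≈ 21% of
predicted lactating intake (15.87 kg/d). At NEm = 0.9 the NEMI model
predicts nonlactating intake of 1.3706% of SBW for the same cow; this
is sometimes quoted rounded as 1.35%, and the package reports the exact
value (checks use a ±0.05 percentage-point tolerance).

## Validation engine

Observed DMI (y) is regressed on predicted DMI (x) by OLS
(y = a + bx + e). The report carries marginal t-tests of a = 0 and
b = 1 (the convention used in published comparison tables) and a joint
2-df F-test of (a, b) = (0, 1), since either reading of "F-test" is
defensible; both are computed, marginal tests are the defaults.

Error summaries:

* RMSD = sqrt(Σ(O−P)²/n), the average deviation about the unity line
  y = x. Divisor n (population-style), configurable via `ddof`.
* Sy.x = RMSE = sqrt(RSS/(n−2)), scatter about the fitted line. RMSD ≥
  RMSE with equality iff a = 0 and b = 1 — so RMSD is the quantity to
  judge a *predictor*, RMSE the quantity to judge the fitted line.

Theil decomposition: SSPE = Σ(O−P)² is split exactly into
n(Ō−P̄)² (bias) + (b−1)²·Σ(P−P̄)² (slope) + RSS (disturbance); the
cross terms vanish by OLS orthogonality, so the three percentages sum
to 100 to machine precision on any input. Percentages are kept at full
precision internally and rounded only at presentation. A perfect
predictor (SSPE = 0) makes the decomposition undefined; the report
flags it instead of emitting numbers.

## Outlier screening

Observed DMI is regressed on {NEm, SBW^0.75, STAGE} (main effects only,
single pass — no iterative re-screening) and observations with
externally studentized residuals > 3 in absolute value are flagged.
External (leave-one-out) studentization is the default, matching the
RSTUDENT convention of the SAS-style workflow this reproduces; internal
studentization is available by option, as is per-stage screening (the
pooled model with the stage dummy is the default because the flagging
regression itself includes STAGE). Under a correct model, P(|t| > 3)
per observation is ≈ 0.003, so clean data of n = 85 flags fewer than
one observation on average — a property the tests verify by
simulation.

## New-model fitting

Both new models are fit by unweighted OLS on treatment means (an
optional weight vector is accepted; weighting by animals-per-mean is
not assumed because it is rarely reported).

* NEMI model: response (DMI·NEm)/SBW^0.75; candidates NEm, NEm²,
  STAGE, NEm×STAGE.
* DMI model: response DMI; candidates SBW^0.75, NEm, NEm², STAGE,
  NEm×STAGE, SBW^0.75×STAGE.

Term selection is deterministic backward elimination at α = 0.05:
interactions first (highest p first, refitting after each drop), then
the quadratic; main effects are never dropped. A surviving quadratic
faces one further rule that operationalizes a visual judgment: the
implied predicted-DMI curve over the observed NEm range (evaluated at
the median SBW for both stages) must be monotone non-decreasing.
A violation — intake predicted to rise at both extremes of the energy
range, which is not biologically sensible for cows in this range —
flags the model as overparameterized and the linear model is reported
with `quadratic_flagged=True`.

Summaries: the lactation intercept of the DMI model divided by mean
milk yield gives intake response per kg milk (3.27/6.56 = 0.50,
3.27/7.3 = 0.45 kg/kg; the ratio is stored exact and rounded to two
decimals only for presentation, against the conventional 0.2 kg/kg).
The lactation energy budget compares the energy demand of lactation
(milk × 0.72 Mcal/kg + 2.2 Mcal/d maintenance increment; 6.9 Mcal/d at
6.56 kg milk) with the energy the intake response supplies
(3.27 × NEm; 4.3 Mcal/d at 1.3 Mcal/kg) — negative balance at moderate
diet energy, consistent with the need for denser diets during
lactation.

## Path analysis

The causal diagram is recursive and just-identified: exogenous NEm and
STAGE, endogenous SBW^0.75 and DMI. For such a system the standardized
coefficients of a covariance-structure (CALIS-style) fit coincide with
standardized slopes from sequential OLS of SBW^0.75 on {NEm, STAGE}
and DMI on {NEm, STAGE, SBW^0.75}; the package therefore uses
sequential standardized OLS rather than general SEM machinery, and the
tests verify the equivalence against a correlation-algebra (Wright's
tracing rules) oracle to 1e-8. The binary STAGE is standardized by its
sample SD — the convention consistent with coefficients from a
covariance-matrix fit. Indirect effects are exact products of the two
constituent paths; totals are direct + indirect. Significance stars at
0.001 and 0.05. No latent variables and no global fit indices: the
model is saturated, so chi-square-type indices are vacuous.

## Synthetic treatment-mean generator

The generator draws per-stage covariates from truncated normal
distributions whose defaults reproduce the published per-stage summary
table (53 nonlactating / 32 lactating; SBW 589±76.7 [420,730] vs
510±69.3 [404,692]; NEm 1.25±0.16 [0.93,1.54] vs 1.21±0.15
[0.99,1.49]; BCS 5.8±0.75 / 4.8±0.58; milk 6.56±2.3 [3.0,11.3]).
The abstract of the source study quotes slightly different nonlactating
summaries (DMI 13.2±2.9, SBW 578±83.9) than its own summary table; the
table values are carried as canonical. Observed DMI is the generating
model's mean (default: DMI_2022) plus Gaussian noise of SD 1.31 kg/d —
the only printed residual-scale estimate for that model.

Numerical choices: truncated normals are sampled by scipy's exact
inverse-CDF (`truncnorm`), which is vectorized and exact at these mild
truncations. Variables are drawn independently by default because the
published summaries contain no covariances; an optional Gaussian-copula
correlation between SBW and NEm reproduces the real-data feature that
cows on energy-dense diets were heavier, which the path-analysis tests
can switch on. Min/max are treated as hard truncation bounds.

What the generator does *not* emulate: within-study animal-level
variance, repeated measures, study-level clustering, breed or
days-in-milk structure, and any real SBW–NEm–BCS dependence beyond the
optional copula. Passing tests therefore demonstrate correctness of
the machinery and recoverability under the stated conditions — not
that the fitted coefficients generalize to independent real data.

## Test design and problem sizes

Hand-checkable examples are frozen from closed-form arithmetic (e.g.
the 4-point unity regression with b = 0.95, SSPE split 75/1.67/23.33).
Implementation-vs-oracle checks use independent routes: explicit
normal-equations inversion, literal leave-one-out refits, and Wright's
rules. Parameter-recovery runs use 200 seeded replicates at n = 500
(300 + 200 per stage), measuring bias against Monte-Carlo error and
95%-CI coverage within 0.95 ± 0.03 on the full candidate design —
straight OLS, since coverage *through* backward elimination is a
post-selection quantity that the selection tests address separately
(interaction retention at 10× its SE, null-quadratic retention near
test size). Moment-fidelity checks run at n = 10,000 per stage against
analytic truncated-normal targets. The whole suite runs in well under
a minute.

## Known limitations

* The published regression tables for the six classical equations rest
  on 85 real treatment means that are not printed anywhere; those exact
  statistics are not reproducible from first principles, and the tests
  assert directions (e.g. equation A's slope > 1 underprediction
  pattern) on synthetic data instead.
* The NEMI/DMI model coefficients are taken as printed constants for
  prediction; refitting on synthetic data recovers them only in
  distribution.
* Backward elimination is one deterministic generalization of
  "non-significant interactions were removed"; other drop orders can
  select different models on borderline data.
* No mixed-effects or study-weighted estimation; the unit is the
  unweighted treatment mean.
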