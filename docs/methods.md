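# Methods

## The problem

When undersized fish are caught by commercial trawlers and discarded, a
fraction survives. Regulators grant landing-obligation exemptions when that
fraction is demonstrably high, but estimating it by holding fish in captivity
is expensive. The cheap alternative is a *vitality indicator* scored on deck:
the presence/absence of six reflexes (body flex, righting, head complex,
evasion, stabilize, tail grab) and four injury types (bruising and punctiform
bleeding, each on head and body). `vitalfit` implements the analytical
pipeline that asks how well such indicators, alone or weighted and combined
with environmental covariates, predict mortality observed at the end of
captive monitoring — both per fish and aggregated per fishing trip.

## Data model

One row per assessed fish, nested in gear deployments within trips. Ten
binary attributes share one orientation: 1 contributes to the index
(reflex impaired, injury present). Injuries are scored in the field on a
0–3 severity scale and dichotomized (present = severity ≥ 1) before any
index is computed; severity-weighted indexing is deliberately out of scope.
The response is mortality at asymptote (1 = dead). Air exposure, when
derived from logged times, is deck minutes plus one third of handling
minutes, because one third of the reflex tests happen in air.

Complete-case filtering is per covariate set: a model using only gear and
sea temperature keeps every record complete for those plus the attributes
and the outcome, so different candidate models may legitimately see
different record counts.

## Models

Every candidate is a binomial logistic GLM

    logit P(dead_i) = α + β' x_i

fitted by IRLS (Fisher scoring) with convergence at max |score| < 1e-8 or
relative deviance change < 1e-10 within 100 iterations. No random effects:
the target is prediction, not variance decomposition, and predicting to a
new random trip level is not meaningful. Quasi-separation is flagged when
fitted probabilities come within 1e-8 of 0/1 on the matching outcome class
(1e-8 being the resolution the score tolerance can certify); flagged or
non-converged fits are excluded from ranking. Linear predictors are capped
at ±30 to keep likelihood terms finite; beyond that point probabilities are
indistinguishable from 0/1 at double precision.

The nine candidate indicator forms: equal-weight reflex-and-injury index
(RI, the mean of the ten binary scores), the weighted index optimized at
fish or trip level, counts of impaired reflexes / present injuries / both,
the categorical A–D vitality grade (unordered factor, reference A), the ten
attributes entered individually ("partitioned"), and a null model. The
null model is intercept-only — it ignores indicators and covariates — and
serves as the Brier-score baseline for the Index of Prediction Accuracy,
which makes its own IPA identically 0 and its Brier score equal to
100·r(1−r) at observed mortality rate r. All other candidates carry the
gear × sea-temperature interaction by default, the covariate set that
dominates model selection on both real-world-shaped and synthetic data; a
full covariate-set sweep is available.

## Weight optimization

The weighted index RI_w = Σ_a w_a·attr_a has weights on the unit simplex
(w_a ≥ 0, Σ w_a = 1; uniform start 0.1 each). Weights are found by nested
optimization: the outer search proposes w, the inner step refits the GLM
and scores it with either

* **fish-level objective** — the model's AIC, or
* **trip-level objective** — the mean over trips of |predicted − observed|
  mean survival, where predicted trip survival averages the per-fish
  predicted survival probabilities (1 − p̂).

Twelve named optimization methods run from the same start; a weighting is
reported *trusted* when all converged methods agree within L∞ 0.05
(configurable). The best run per (level, covariate set) is the converged
one with the lowest objective, ties broken by wall time then registry
order. Per-attribute relevance follows the ≤ 0.10 / ≤ 0.20 / > 0.20
little/medium/high convention, with weights > 0.30 from unusually slow
runs (above the batch's 95th wall-time percentile by default) flagged as
outliers.

Numerical choices that matter:

* The named methods are unconstrained, so the search runs over ten
  unconstrained parameters mapped through a softmax onto the simplex.
  The softmax has a flat direction (adding a constant changes nothing);
  in practice no method is troubled by it. Weights below 5e-3 are snapped
  to exact zeros and the vector renormalized for reporting — softmax can
  only approach zero asymptotically, while irrelevant attributes should
  report as exactly 0. Snapping is reverted for a run if it would break
  the descent contract.
* The outer objective is normalized by its start value so that AIC-scale
  (~10³) and trip-error-scale (~10⁻¹) problems present comparable
  gradients and stopping tolerances.
* Finite-difference gradients use step 1e-5: the inner IRLS resolves the
  objective only to ~1e-7 relative, so smaller steps measure noise.
* A constant index column (degenerate weights on constant attributes) is
  collinear with the intercept and is dropped for that evaluation; an
  inner fit that fails or separates scores +∞, which keeps the outer
  search alive while making the point unattractive — this is also how
  "n of m runs converged" bookkeeping arises.
* Equal-weight vectors are evaluated as the plain arithmetic mean rather
  than a dot product, so the reduction of the weighted index to the
  equal-weight index is exact in floating point, not only mathematically.
* Registry mapping onto SciPy: ucminf → BFGS (∞-norm gradient test),
  nlm → Newton-CG with numeric gradient, nlminb → TNC, spg → SLSQP,
  bobyqa and hjkb → Powell variants, newuoa → COBYLA, nmkb → adaptive
  Nelder-Mead. Method-for-method parity with the original routines is not
  promised; the consensus check is what carries the trust argument.
  Each method may spend up to `max_evaluations` objective calls
  (default 4000); derivative-free simplex methods need most of that in
  ten dimensions.

## Evaluation

Brier scores are reported ×100 (a constant-0.5 forecast scores 25.0). IPA
is 100·(1 − Brier_model/Brier_null). Confusion matrices classify a fish as
survivor when predicted death probability is below the cutoff (default
0.5; the field convention consistent with the 0.5 high/low survival line,
and configurable since the original cutoff is not stated). Survivors are
the positive class: TP are correctly predicted survivors, TN correctly
predicted deaths. Survival ratios are observed/predicted mean survival per
trip, summarized per gear as mean (min–max) across trips, with a
management call of *high* only when strictly above 0.50. Evaluation is
in-sample by design: the upstream finding is that these models do not fit
well enough to justify building held-out predictive claims, so no
cross-validation machinery exists here.

## Synthetic data generator

The generator reproduces the hierarchical structure the analysis assumes,
with known ground truth: 12 beam-trawl (BT2) trips and 2 otter-trawl (OTB)
trips; 3–6 / 6–8 deployments per trip (chosen so expected totals match the
two fleets' 57 and 14 monitored deployments); 3–19 / 12–44 fish per
deployment. Deployment covariates are uniform over each fleet's operating
ranges (BT2: 45–195 min tows, 5–80 m, 5–19 °C; OTB: 180–270 min, 44–66 m,
8–16 °C); catch weights are log-normal matched to mean ± SD 1118 ± 874 kg
(BT2) and 674 ± 350 kg (OTB); air exposure is normal truncated at zero
(10 ± 5 and 17 ± 18 min); length is normal 23 ± 2 cm.

A single latent stressor — the standardized linear combination of
duration, air exposure and sea temperature — drives each attribute through
logistic curves expit(a0_a + a1_a·s). Mortality is Bernoulli with
logit P(dead) = α + Σ γ_a·attr_a + covariate terms including a gear ×
sea-temperature interaction. Defaults put the strongest effects on body
and head bruising and give an overall mortality rate near one third;
attribute intercepts yield impairment prevalences of roughly 20–40%, with
longer tows and air exposures (the otter-trawl profile) shifting
impairment upward. These coefficient defaults are a modelling convention
calibrated to the study's reported operating conditions — they are not
estimates of any field dataset, and the generator's attribute prevalences
should not be quoted as such. Missingness is injected completely at random
in total catch (4%), length (3%) and air exposure (5%), mirroring the
variables that carry missing values in field exports. The categorical
grade is derived from the impaired-reflex count (A: 0, B: 1–2, C: 3–5,
D: 6) — an explicit, configurable convention, since field scoring has no
formal mapping.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers known structure (a causal attribute gets the
dominant weight; effects are estimated consistently; aggregation to trips
behaves as the closed forms dictate). They do not show that real reflex
scores are conditionally independent given a single stressor index, nor
that real vitality–survival relationships are stable across fleets — the
generator is deliberately simpler than the biology.

## Degenerate inputs and tie-breaks

Missing attribute scores are an error, never a renormalized denominator —
a silent denominator change would alter the index scale. Single-gear data
reject gear terms (rank deficiency) rather than silently dropping the
dummy. A survival ratio of exactly 0.50 is *low*. A relevance weight of
exactly 0.10 is *little*, 0.20 *medium*, 0.30 *high* (the outlier rule
needs > 0.30 *and* a slow run). Weight vectors are accepted when they sum
to 1 within 0.015, so published two-decimal weight rows round-trip.

## Problem sizes

Tests and the acceptance script run on generated data at the study's own
scale (≈ 1000 fish, 14 trips, 71 deployments) or n = 2000 for
parameter-recovery experiments; recovery checks use 10–20 seeds with
per-method evaluation budgets of 1200–4000 objective calls.

## Known limitations

* The trip-level objective is genuinely flatter and multimodal: different
  optimizers reach different weightings with nearly equal error, and the
  consensus check frequently (and correctly) reports *not trusted* there.
  This mirrors the instability of trip-level weighting reported for the
  original data and is surfaced, not hidden.
* No GLMMs, splines, regularization or ROC analysis; out of scope by
  design.
* The generator's single-stressor assumption cannot produce attributes
  with conflicting stressor responses (e.g. one reflex improving while
  another degrades).
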