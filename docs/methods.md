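# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of `immunometa`. It documents
what the code computes; every number quoted here is produced by the test
suite or the pipeline itself.

## 1. Study setting

The package analyses the pooled evidence of six single-arm anti-PD-1
studies: melanoma monotherapy (n = 119, ORR 20.17%), dMMR/MSI-H solid
tumors monotherapy (n = 100, ORR 49%), a pan-solid dose-escalation cohort
(n = 30, ORR 16.7%), gastric/GEJ cancer with oxaliplatin + capecitabine
(n = 35, ORR 60%), gastric/GEJ with irinotecan (n = 58, ORR 27.6%), and
TNBC with gemcitabine + cisplatin (n = 31, ORR 80.6%) — 373 patients in
all. No patient-level data are deposited anywhere; the unit of real input
is the study summary (counts, rates, medians). Everything patient-level is
synthetic by design, which is what makes the downstream stages testable.

## 2. Random-effects meta-analysis (`bayes_meta`)

Model: x_i ~ Binomial(n_i, p_i), logit p_i = θ_i, θ_i ~ N(μ, τ²).

* μ prior N(0, 100²) on the logit scale. The scale parameter is read as a
  standard deviation: the weakly-informative alternative N(0, 10²) only
  makes sense as a *scale* contrast, and a logit SD of 100 is flat over any
  realistic proportion. Both are exposed in `PriorSpec`.
* τ prior Half-Normal(2) by default, Half-Cauchy(2.5) as the alternative;
  the source analysis never states its τ prior, so this is a package
  choice, recorded here once.
* Sampler: Metropolis-within-Gibbs, vectorized across chains — elementwise
  Gaussian random-walk updates for θ with Robbins–Monro step adaptation
  to a 0.44 acceptance rate during burn-in, a conjugate Gibbs draw for μ,
  and a random-walk update for log τ (Jacobian included). Defaults: 10,000
  iterations, 2,000 burn-in, 4 chains. Convergence is monitored by split
  R̂ (flagging > 1.05) and a first-order-autocorrelation ESS; multiple
  chains are used even though a single schedule would be cheaper, because
  convergence cannot be asserted from one chain.
* τ = 0 degenerates the model to a common effect; the sampler then walks μ
  directly against the pooled binomial likelihood (this path also serves
  single-study inputs, which cannot identify τ and must pin it).
* Zero cells need no continuity correction in the likelihood. The +0.5
  adjustment exists only inside the moment-based s² of I²
  (v_i = 1/x_i + 1/(n_i − x_i) is undefined at the boundary), with
  s² = (k−1)Σw / ((Σw)² − Σw²), w_i = 1/v_i. I² is computed draw-wise as
  τ²/(τ² + s²).
* Pooled odds ratios for single-arm data require a reference proportion;
  there is no natural control arm, so p₀ is an explicit argument with no
  claim that any particular p₀ reproduces an externally printed OR.
* The normal-likelihood variant (`fit_normal_random_effects`) is
  conjugate in everything but τ; at τ fixed to 0 the posterior of μ is
  drawn i.i.d. from its closed form. That closed form is also exported
  (`normal_fixed_effect_posterior`) and is the oracle the sampler is
  tested against.
* Publication bias: "funnel asymmetry" is operationalized as an
  inverse-variance weighted regression of effect on SE with a permutation
  p-value (no formula for a "funnel plot probability distribution" exists
  in the source text). Trim-and-fill is Duval–Tweedie with the L0
  estimator, iterating trim → re-estimate → recount to convergence and
  filling mirror images about the trimmed fixed-effect centre. The
  implementation reproduces R `metafor::trimfill` exactly on every dataset
  tried during development (the package's `side="right"` — the excess
  side — corresponds to metafor's `side="left"` imputation side). L0 has
  low power on plain Gaussian draws: suppressing 3 of 20 such studies
  leaves the first-pass estimate at 0 for this implementation *and* for
  metafor, because the fixed-effect centre absorbs the truncation. The
  recovery test therefore simulates the textbook geometry the method
  assumes: a quasi-balanced funnel (z-scores on a symmetric grid plus
  N(0, 0.15) noise, SE ~ U(0.05, 0.4)), where the modal k₀ over 50
  replicates is exactly the 3 suppressed studies.

## 3. Survival reconstruction and pooling (`survival_meta`)

Arm-level Weibull S(t) = exp(−(t/λ)^k), λ = median/(ln 2)^{1/k}. A reported
95% CI for the median maps to se(log λ) = (ln U − ln L)/(2·1.96). Landmark
fitting linearizes through ln(−ln S) = k ln t − k ln λ (exact with two
landmarks). HRs between arms assume proportional hazards at a shared shape,
HR = (λ_b/λ_a)^k, with SEs combined in quadrature and scaled by k. The
shared shape defaults to k = 1 (exponential): medians alone cannot identify
a shape, and k = 1 keeps median-only inputs fully identified while reducing
the HR to the inverse median ratio. Log-HRs pool through the normal
random-effects model above. Survival-curve digitization is out of scope;
landmark probabilities stand in for curve data. Landmark *rates* (e.g.
12-month OS) pool through `bayes_meta` on counts reconstructed with
`counts_from_rate` — no separate machinery.

## 4. Network meta-analysis (`nma`)

All six studies are single-arm, so literal within-study contrasts do not
exist. The default model is therefore arm-based:
logit p_arm = m + d_t + u_study, u ~ N(0, σ²), d_ref = 0 — treatment
contrasts are identified through the shared intercept and the exchangeable
study effects, an interpretive choice recorded in the NMA output metadata.
A contrast-based Lu–Ades consistency model is provided for networks that do
contain multi-arm studies (it refuses all-single-arm input and directs the
caller to the arm-based model); its multi-arm random-effect correlation is
approximated as independent per non-baseline arm.

Ranking: rank probabilities come from draw-wise strict ordering of the d_t
(ties broken by an infinitesimal random jitter — measure-zero for
continuous draws), SUCRA_t = Σ_{r<k} CumP(rank ≤ r)/(k−1). Two identities
hold by construction and are asserted in tests: Σ_t SUCRA_t = k/2 (to
1e−9) and SUCRA → 1 − SUCRA under a direction flip.

Node splitting separates the evidence for a comparison (a, b): direct =
studies containing both treatments or, in all-single-arm networks, studies
of a and b sharing a stratum (a configurable study → stratum map; tumor
type in the pipeline preset); indirect = the remaining network. The two
estimates come from independent fits, and the two-sided Bayesian
p = 2·min(P(Δ>0), P(Δ<0)) is floored at 1/draws. This separate-fits
reading (rather than a joint model with an inconsistency parameter) keeps
the direct and indirect posteriors genuinely independent.

## 5. Biomarker screening (`ml_screen`)

The in-package learner is L1-penalized logistic regression minimizing
mean NLL + λΣ|β_j| (intercept unpenalized) by cyclic coordinate descent
with the global quadratic majorization bound 1/4 on the logistic curvature;
the penalized objective is non-increasing across updates and iteration
stops at a 1e−6 maximum coefficient change or `maxit` (default 1000).
Columns are standardized internally by default. At λ = 0 the fit matches a
Newton–Raphson MLE oracle to 1e−4; at λ → ∞ it collapses to the
closed-form intercept logit(ȳ).

* λ selection: stratified K-fold CV (default 5) minimizing mean squared
  error between predicted probability and outcome, ties broken toward the
  larger λ (the sparser model).
* ROC/AUC: Mann–Whitney with ties counted ½; percentile bootstrap CI.
* Variable importance: VIS_j = |β_j·sd_j| normalized to sum 1
  (standardized-coefficient reading) or a permutation-importance variant
  (mean AUC drop, negatives floored at 0). The screening thresholds are
  VIS ≥ 10% for the efficacy outcome and ≥ 8% for the irAE outcome, both
  configurable. No external definition of VIS for any specific learner
  exists, so both definitions are exposed and the choice is logged in the
  output.
* AUC-contribution stability: contribution of feature j = AUC(full panel)
  − AUC(panel − j), refitted per bootstrap resample (default B = 500); a
  singleton panel is compared against the intercept-only model (AUC 0.5).
  Leave-one-feature-out under bootstrap is one reasonable reading of a
  per-biomarker "AUC contribution"; it is the one implemented.
* Boosted trees and random forests are not reimplemented: any object with
  `fit`/`predict_proba` plugs into the same surface, and the published
  hyperparameter sets ship as recorded presets (`XGB_PRESET`,
  `RF_PRESET`).
* The 7:3 split of 373 is pinned to (273, 100) in the pipeline preset.
  Literal rounding gives 261/112; the published arithmetic is 273/100, so
  the splitter takes an explicit train size and the preset supplies it.
  Splits are outcome-stratified via largest-remainder apportionment.

## 6. Score, stratification, decision curves (`score_strat`)

The default score uses seven factors (+2 KMT2D, +1 NLR decrease, +1 PD-L1
CPS ≥ 1, +1 eotaxin high, −1 irinotecan, −2 NLR ≥ 4, −1 VEGF high);
exhaustive enumeration of all 2⁷ combinations spans exactly the integers
−4…+5. An eighth factor (baseline thyroid dysfunction, −1) is available
behind `include_thyroid` but off by default: including it would extend the
minimum to −5, contradicting the stated −4…5 range, so the seven-factor
set is canonical. Stratification cutoffs: benefit ≤0 / 1–2 / ≥3, risk
≥1 / −1–0 / ≤−2.

Kaplan–Meier (Greenwood CIs), the two-group log-rank test, and univariate
Cox regression (Efron tie handling — monthly-resolution data are heavily
tied — Newton–Raphson, Wald CIs) are delegated to `lifelines`, which
implements exactly these estimators; the module adds the domain surface,
the monotone-likelihood flag (a group without events), and input
validation. The time-to-event reading of an irAE hazard ratio between risk
strata is time-to-first grade ≥3 irAE as a cause-specific hazard — the
source text never defines one, so this is an interpretation, recorded
here.

Decision curves need probabilities, not integer scores; the score is
calibrated to the outcome by a two-parameter logistic fit on the training
split. NB_model = TP/N − (FP/N)·p_t/(1−p_t) at classification threshold
score ≥ p_t, NB_all = π − (1−π)·p_t/(1−p_t), NB_none ≡ 0; a perfect
predictor attains NB = π at every threshold, which bounds NB_model.

## 7. The synthetic cohort (`synthetic_cohort`)

The generator is first-class, tested code. What it emulates, per study:
published enrolment, marginal ORR and grade ≥3 TRAE rate; melanoma subtype
fractions (18.5% cutaneous / 52.1% acral / 19.3% mucosal, remainder
generated as "other" rather than renormalizing); dMMR/MSI-H status fixed at
81% within the dMMR study; KMT2D prevalence 72.6% there and 30% elsewhere
(consistent with the implied cohort-wide ~41%); PD-L1 CPS ≥ 1 at 34.3% in
the gastric studies and 45% elsewhere; eotaxin-high 40% (only an
outcome-conditional prevalence is published, so this is a free parameter);
VEGF-high 35%, MCP-1-high 40%, NLR ≥ 4 30%, TMB-high 30% (60% in dMMR);
NLR change (decrease/stable/increase) at (25/50/25)%.

Response model: per-study logistic with biomarker coefficients shared
across studies. Intercepts are root-found (Brent, 1e−10) so each study's
*expected* marginal ORR equals its published value exactly — an identity
the tests assert by enumeration. Coefficients are least-squares calibrated
(exact enumeration over the joint flag distribution, intercepts re-solved
at every step) against the published cohort-wide biomarker-conditional
response pairs, bounded to log-odds [0, 4]: unbounded optimization
collapses to a deterministic response rule with coefficients ~40, which
destroys the probabilistic structure. The system is overconstrained —
with the bound, the model lands at e.g. KMT2D-conditional response
0.586/0.226 against the published 0.698/0.150 — so tests validate the
generated rates against the generator's own analytic values plus the
published direction and magnitude, not the unattainable printed pairs.
The irAE model is a single cohort-wide logistic (intercept + NLR ≥ 4,
irinotecan, VEGF-high) calibrated the same way; its implied overall grade
≥3 irAE rate (~15%) follows from the published conditional pairs, which
are arithmetically incompatible with the separately printed pooled 5.8%.
The conditional pairs drive the risk stratification and therefore win.

Survival: PFS and OS are Weibull with per-study shape (default k = 1 —
no fitted shapes are published) and scale set so the reference-stratum
median matches the published median; hazard effects are multiplicative
(PFS: HR 0.31 for NLR decrease; OS: HR 0.47 for eotaxin-high).
Administrative censoring at 24 months, the longest published landmark.
The dMMR study's median PFS was "not reached"; it is represented by a
latent 30-month median that the censored curve never crosses. OS medians
other than melanoma's 16.59 months are not all published and are set to
plausible per-study defaults (36, 12, 18, 9, 21 months).

Responders split CR/PR at 15/85%, non-responders SD/PD at 40/60% — only
the CR+PR margin is calibrated; the four-level split is cosmetic.
Biomarker flags are independent within study (no joint distribution is
published) except dMMR status and melanoma subtype; the coefficient maps
live in the config so correlations can be added later.

Missingness: `inject_missingness` masks fields independently at their
rates (≤ 15% by default, override flag up to 50%), with dict-valued rates
conditioning on a fully observed column (MAR); the unmasked cohort is the
ground truth for post-imputation comparison. Imputation is
single-imputation chained equations (ridge-logistic draws for binaries,
normalized one-vs-rest for categoricals, linear-Gaussian for continuous
fields), deterministic under a fixed seed; Rubin pooling across multiple
imputations is out of scope.

What the generator does *not* emulate: the authors' unpublished joint
patient-level distribution, raw cytokine concentrations (only thresholded
flags), non-proportional hazards, correlated biomarkers, and informative
missingness. Tests passing on this cohort show the *machinery* is correct
under the published margins — not that real patients behave this way.

## 8. Problem sizes and numerical choices

Replicate counts and MCMC schedules in the test suite are sized so checks
stay sharp while the whole suite runs in about a minute on one CPU:
sampler-oracle checks use 12k iterations; coverage calibration uses 100
replicate meta-analyses at 1.5k iterations × 2 chains; recovery
simulations use 4k iterations; the log-rank type-I calibration uses 1,000
replicates; generator-fidelity checks sample at 20×–100× enrolment and
5,000 patients for hazard-ratio recovery. Root-finding tolerances: 1e−10
(intercept calibration), 1e−6 (coordinate descent), 1e−8 (ridge-logistic
Newton). All randomness flows through `numpy.random.default_rng` with
explicit seeds; the pipeline derives per-stage seeds from one global seed
by hashing, so stages re-run independently yet reproducibly, and repeated
runs are byte-identical.

## 9. Known limitations

* Published pooled values that depend on the authors' unavailable
  patient-level data or on an undefined single-arm "control" (pooled
  OR = 4.82, HR = 0.41/0.37, I² = 38.7%, specific AUCs and SUCRA
  percentages) are reproduced in structure, not in value.
* The published overall SUCRA set sums to 250% for four treatments,
  violating the Σ = k/2 identity; no standard SUCRA computation can
  produce it, and the package's identity-conserving values are the ones
  tested.
* The exact upper Clopper–Pearson endpoint for 25/31 is 92.548%; the
  published 92.6% is a double rounding. Tests compare at printed precision
  with that half-ULP allowance.
* The arm-based NMA identifies contrasts through exchangeability across
  single-arm studies; it cannot deliver the strength of randomized
  within-study evidence, and its node-split "direct evidence" (shared
  stratum) is an analysis convention, not a trial design.
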