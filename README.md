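# immunometa

Integrated *efficacy–prediction–safety* analysis of pooled single-arm
immunotherapy trials.

Anti-PD-1 agents show strongly heterogeneous response across tumor types:
the same antibody can produce an objective response rate (ORR) of 8.7% in
mucosal melanoma and 80.6% in triple-negative breast cancer under
chemotherapy combination. When the evidence base is a handful of single-arm
phase I/II studies, three questions have to be answered together: *how
effective is the drug overall and per subgroup* (meta-analysis), *which
patients benefit or get harmed* (biomarker screening), and *which regimen
should a given patient receive* (regimen ranking plus benefit/risk
stratification). `immunometa` implements that whole chain as a tested,
reusable Python pipeline, runnable end to end on a synthetic patient cohort
that emulates six published single-arm trials (n = 119, 100, 30, 35, 58, 31;
373 patients total), so every stage is verifiable without access to the
original patient-level data.

## What is inside

| Module | Contents |
|---|---|
| `core_data` | domain types, cohort CSV I/O, count reconstruction from printed rates, exact (Clopper–Pearson) and Bayesian binomial intervals, chained-equation imputation |
| `synthetic_cohort` | the six-study synthetic cohort generator with calibrated biomarker-conditional response/irAE models and Weibull survival |
| `bayes_meta` | Bayesian binomial-logit random-effects meta-analysis (adaptive Metropolis-within-Gibbs), draw-wise I², subgroups, meta-regression, leave-one-out and prior-swap sensitivity, Egger-type funnel asymmetry, Duval–Tweedie trim-and-fill |
| `survival_meta` | Weibull reconstruction from medians/landmarks, hazard ratios under a shared shape, Bayesian log-HR pooling |
| `nma` | arm-based and contrast-based network meta-analysis, rank probabilities, SUCRA, node-splitting consistency checks |
| `ml_screen` | L1-penalized logistic regression by coordinate descent, CV for λ, Mann–Whitney ROC/AUC, variable-importance screening, bootstrap AUC-contribution stability |
| `score_strat` | the 7-factor weighted benefit/risk score, stratification, Kaplan–Meier / log-rank / Cox comparisons, decision-curve analysis |
| `pipeline` / `cli` | end-to-end orchestration with per-stage seeds and machine-readable outputs; `immunometa` console command |

## Core models

**Pooled binary outcome.** For study *i* with *x<sub>i</sub>* responders of
*n<sub>i</sub>*,

> x<sub>i</sub> ~ Binomial(n<sub>i</sub>, p<sub>i</sub>),  logit p<sub>i</sub> = θ<sub>i</sub>,  θ<sub>i</sub> ~ N(μ, τ²)

with μ ~ N(0, 100²) (flat on the logit scale; N(0, 10²) as the
weakly-informative alternative) and τ ~ Half-Normal(2). Heterogeneity is the
draw-wise I² = τ²/(τ² + s²), where s² is the typical within-study variance
of the observed logits. Pooled odds ratios against a reference proportion
p₀ are computed draw-wise as exp(μ − logit p₀).

**Survival.** Arm-level curves are Weibull, S(t) = exp(−(t/λ)^k), anchored
on reported medians (λ = m/(ln 2)^{1/k}) or fitted to landmark rates via
ln(−ln S) = k ln t − k ln λ. Between arms at a shared shape,
HR = (λ_b/λ_a)^k; log-HRs pool through a normal-likelihood random-effects
model.

**Ranking.** Because all six studies are single-arm, the network model is
arm-based: logit p = m + d<sub>t</sub> + u<sub>study</sub>,
u ~ N(0, σ²), with the reference regimen's d pinned at 0. SUCRA is the
normalized sum of cumulative rank probabilities (Σ<sub>t</sub> SUCRA = k/2 by
construction).

**Scoring.** Seven integer-weighted factors (KMT2D mutation +2, NLR decrease
+1, PD-L1 CPS ≥ 1 +1, high eotaxin +1, irinotecan combination −1, baseline
NLR ≥ 4 −2, high VEGF −1) give totals in −4…+5; benefit strata ≤0 / 1–2 /
≥3, risk strata ≥1 / −1–0 / ≤−2. Net benefit at threshold p<sub>t</sub> is
TP/N − (FP/N)·p<sub>t</sub>/(1−p<sub>t</sub>).

## Worked example

```python
import numpy as np
from immunometa import bayes_meta as bm
from immunometa import core_data as cd
from immunometa import score_strat as st
from immunometa import synthetic_cohort as sc

# exact binomial interval for the 2/23 mucosal melanoma stratum
print(cd.binom_interval(2, 23))          # (0.0107, 0.2804)

# synthetic 373-patient cohort, scored and stratified
coh = sc.generate_cohort(sc.default_config(), seed=5)
scores = st.score_cohort(coh)
sf = st.strata_frame(scores)
resp = coh.table.response.isin(["CR", "PR"]).astype(float)
print({b: round(float(resp[sf.benefit == b].mean()), 3)
       for b in ("low", "medium", "high")})
# {'low': 0.171, 'medium': 0.432, 'high': 0.8}

# random-effects pooling of the six study-level ORRs
cfg = sc.default_config()
x = np.array([float(cd.counts_from_rate(s.target_orr, s.n_enrolled))
              for s in cfg.studies])
n = np.array([float(s.n_enrolled) for s in cfg.studies])
mi = bm.MetaInput(tuple(s.study_id for s in cfg.studies), x, n, p0=0.15)
fit = bm.fit_random_effects(mi, mcmc=bm.McmcSettings(seed=1))
print(round(fit.summaries["pooled_p"]["median"], 3))   # 0.407
print(round(bm.bayesian_i2(fit, mi)["median"], 3))     # 0.948
```

The stratified ORRs (17% → 43% → 80% across benefit strata) mirror the
ordering the scoring system is built to produce; the pooled proportion 0.407
is the random-effects mean response over the six heterogeneous studies, and
the I² near 0.95 reflects the very large between-study spread of ORRs
(0.167 to 0.806) relative to their binomial noise.

The same chain runs from the shell:

```bash
immunometa all --seed 1 --out runs/demo   # writes CSV/JSON per stage + report.md
```

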