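"""Integrated 7-factor benefit/risk score, stratification, survival
comparison, and decision-curve analysis.

The score sums integer points over seven patient factors: KMT2D mutation +2,
post-treatment NLR decrease +1, PD-L1 CPS >= 1 +1, high eotaxin +1,
irinotecan combination -1, baseline NLR >= 4 -2, high VEGF -1 (achievable
totals span exactly -4 .. +5).  An optional eighth factor (baseline thyroid
dysfunction, -1) is off by default because it would extend the minimum to
-5.  Stratification: benefit low <= 0 / medium 1-2 / high >= 3; risk low
>= 1 / medium -1..0 / high <= -2.

Kaplan-Meier (Greenwood CIs), the two-group log-rank test, and the
univariate Cox model (Efron ties, Newton-Raphson) are delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import Cohort

__all__ = [
    "ScoreWeights",
    "StratumAssignment",
    "compute_score",
    "score_cohort",
    "assign_strata",
    "enumerate_scores",
    "km_estimate",
    "log_rank",
    "cox_hr",
    "decision_curve",
    "score_to_probability",
]

DEFAULT_WEIGHTS: dict[str, int] = {
    "kmt2d_mut": 2,
    "nlr_decrease": 1,
    "pdl1_cps_pos": 1,
    "eotaxin_high": 1,
    "irinotecan": -1,
    "nlr_baseline_ge4": -2,
    "vegf_high": -1,
}
THYROID_EXTENSION = {"thyroid_dysfunction_baseline": -1}


@dataclass(frozen=True)
class ScoreWeights:
    weights: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    include_thyroid: bool = False

    def items(self):
        w = dict(self.weights)
        if self.include_thyroid:
            w.update(THYROID_EXTENSION)
        return w.items()


@dataclass(frozen=True)
class StratumAssignment:
    benefit: str  # low / medium / high
    risk: str


def _factor_value(row: Mapping, factor: str):
    """Factor presence from a patient record row; None when missing."""
    if factor == "nlr_decrease":
        v = row.get("nlr_change")
        return None if v is None or (isinstance(v, float) and np.isnan(v)) \
            else int(v == "decrease")
    if factor == "irinotecan":
        v = row.get("regimen")
        return None if v is None else int(v == "irinotecan")
    v = row.get(factor)
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return int(v)


def compute_score(patient: Mapping, weights: ScoreWeights | None = None) -> int:
    """Integer weighted score of one patient record (a mapping of fields)."""
    weights = weights or ScoreWeights()
    total = 0
    for factor, pts in weights.items():
        v = _factor_value(patient, factor)
        if v is None:
            raise ValueError(
                f"factor {factor!r} is missing; run imputation first")
        total += pts * v
    return total


def score_cohort(cohort: Cohort,
                 weights: ScoreWeights | None = None) -> pd.Series:
    """Vectorized scores for every patient in a cohort."""
    weights = weights or ScoreWeights()
    df = cohort.table
    total = np.zeros(len(df), dtype=int)
    for factor, pts in weights.items():
        if factor == "nlr_decrease":
            col = df["nlr_change"]
            if col.isna().any():
                raise ValueError("nlr_change has missing values")
            v = (col == "decrease").astype(int).to_numpy()
        elif factor == "irinotecan":
            v = (df["regimen"] == "irinotecan").astype(int).to_numpy()
        else:
            col = df[factor]
            if col.isna().any():
                raise ValueError(f"{factor} has missing values")
            v = col.astype(int).to_numpy()
        total += pts * v
    return pd.Series(total, index=df.index, name="score")


def enumerate_scores(weights: ScoreWeights | None = None) -> np.ndarray:
    """All achievable totals over the 2^m presence/absence combinations."""
    weights = weights or ScoreWeights()
    pts = [p for _, p in weights.items()]
    totals = {0}
    for p in pts:
        totals = {t + b * p for t in totals for b in (0, 1)}
    return np.array(sorted(totals))


def assign_strata(score: int) -> StratumAssignment:
    """Benefit and risk stratum labels for an integer score."""
    benefit = "low" if score <= 0 else ("medium" if score <= 2 else "high")
    risk = "high" if score <= -2 else ("medium" if score <= 0 else "low")
    return StratumAssignment(benefit, risk)


def strata_frame(scores: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame({"score": scores})
    out["benefit"] = ["low" if s <= 0 else "medium" if s <= 2 else "high"
                      for s in scores]
    out["risk"] = ["high" if s <= -2 else "medium" if s <= 0 else "low"
                   for s in scores]
    return out


# ---------------------------------------------------------------------------
# Survival comparison (lifelines-backed)
# ---------------------------------------------------------------------------

def km_estimate(times, events, level: float = 0.95) -> dict:
    """Product-limit survival curve with Greenwood confidence band.

    Returns the step function (times, survival, CI columns) and the median
    survival (NaN-flagged as undefined when the curve never reaches 0.5).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative times")
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter(alpha=1 - level)
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    med = kmf.median_survival_time_
    return {
        "time": sf.index.to_numpy(),
        "survival": sf.iloc[:, 0].to_numpy(),
        "ci_lower": ci.iloc[:, 0].to_numpy(),
        "ci_upper": ci.iloc[:, 1].to_numpy(),
        "median": float(med) if np.isfinite(med) else float("nan"),
        "median_defined": bool(np.isfinite(med)),
    }


def log_rank(group_a: tuple, group_b: tuple) -> dict:
    """Two-group log-rank test (hypergeometric variance, 1 df chi-square)."""
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return {"statistic": 0.0, "p_value": 1.0}
    from lifelines.statistics import logrank_test
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"statistic": float(res.test_statistic),
            "p_value": float(res.p_value)}


def cox_hr(group_label, times, events) -> dict:
    """Univariate Cox PH hazard ratio of group 1 versus group 0.

    Efron tie handling, Newton-Raphson maximization, Wald CI (all via
    lifelines).  A group without events leaves the likelihood monotone; the
    result is flagged and the CI unbounded.
    """
    g = np.asarray(group_label, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events at all")
    monotone = (e[g == 1].sum() == 0) or (e[g == 0].sum() == 0)
    from lifelines import CoxPHFitter
    df = pd.DataFrame({"g": g, "t": t, "e": e})
    cph = CoxPHFitter()
    import warnings
    with warnings.catch_warnings():
        if monotone:
            warnings.simplefilter("ignore")
        cph.fit(df, duration_col="t", event_col="e")
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    z = 1.959963984540054

    def safe_exp(v):  # monotone likelihoods overflow plain math.exp
        return float(np.exp(np.clip(v, -700, 700)))

    return {
        "hr": safe_exp(coef),
        "ci": (safe_exp(coef - z * se), safe_exp(coef + z * se)),
        "log_hr": coef,
        "se_log_hr": se,
        "monotone_likelihood": monotone,
    }


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

def score_to_probability(scores, outcomes) -> "np.ndarray":
    """Logistic calibration of the integer score to an event probability.

    Fits P(outcome | score) = invlogit(a + b * score) by Newton-Raphson and
    returns the per-patient calibrated probabilities.
    """
    s = np.asarray(scores, dtype=float)
    yy = np.asarray(outcomes, dtype=float)
    X = np.column_stack([np.ones_like(s), s])
    beta = np.zeros(2)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-9)
        step = np.linalg.solve((X * w[:, None]).T @ X + 1e-9 * np.eye(2),
                               X.T @ (yy - mu))
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return 1 / (1 + np.exp(-np.clip(X @ beta, -30, 30)))


def decision_curve(risk_scores, outcomes,
                   thresholds=None) -> pd.DataFrame:
    """Net benefit of the model versus treat-all and treat-none.

    NB_model(p_t) = TP/N - (FP/N) * p_t/(1-p_t) classifying positive at
    score >= p_t; NB_all = pi - (1-pi) * p_t/(1-p_t); NB_none = 0.
    Thresholds equal to 1 are dropped with a warning.
    """
    p = np.asarray(risk_scores, dtype=float)
    yy = np.asarray(outcomes, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risk scores must be probabilities in [0,1]")
    if thresholds is None:
        thresholds = np.arange(0.05, 0.51, 0.01)
    thresholds = np.asarray(list(thresholds), dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        import warnings
        warnings.warn("thresholds outside (0,1) excluded from the grid")
        thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    N = len(yy)
    pi = yy.mean()
    rows = []
    for pt in thresholds:
        pos = p >= pt
        tp = int((pos & (yy == 1)).sum())
        fp = int((pos & (yy == 0)).sum())
        odds = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "nb_model": tp / N - (fp / N) * odds,
            "nb_all": pi - (1 - pi) * odds,
            "nb_none": 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["N"] = N
    out.attrs["prevalence"] = float(pi)
    return out
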