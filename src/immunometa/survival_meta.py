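"""Weibull reconstruction of arm-level survival and hazard-ratio pooling.

Published single-arm studies report medians, confidence intervals, and
landmark survival rates rather than patient-level times.  This module
rebuilds a parametric Weibull curve S(t) = exp(-(t/lambda)^k) for each arm
from those summaries, derives hazard ratios between arms under a shared
shape (proportional hazards), and pools log-hazard-ratios with the
normal-likelihood Bayesian random-effects model from :mod:`bayes_meta`.

The default shared shape is k = 1 (exponential): published medians alone
cannot identify a shape, and under k = 1 the HR reduces to the inverse ratio
of medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bayes_meta import McmcSettings, MetaResult, PriorSpec, \
    fit_normal_random_effects

__all__ = [
    "WeibullFit",
    "HrEstimate",
    "weibull_from_median",
    "weibull_from_landmarks",
    "hr_between",
    "pool_log_hr",
]


@dataclass(frozen=True)
class WeibullFit:
    """Weibull survival parameters, S(t) = exp(-(t/scale)^shape)."""

    shape: float
    scale: float
    se_log_scale: float | None = None
    source: str = "median_only"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))

    @property
    def median(self) -> float:
        return self.scale * math.log(2) ** (1.0 / self.shape)


@dataclass(frozen=True)
class HrEstimate:
    log_hr: float
    se_log_hr: float | None
    label: str = ""

    def __post_init__(self) -> None:
        if self.se_log_hr is not None and self.se_log_hr <= 0:
            raise ValueError("se_log_hr must be positive")

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)


def weibull_from_median(
    median: float,
    ci: tuple[float, float] | None = None,
    shape: float = 1.0,
) -> WeibullFit:
    """Weibull fit anchored on a reported median: scale = m / (ln 2)^(1/k).

    A reported 95% CI for the median yields se_log_scale =
    (ln upper - ln lower) / (2 * 1.96), carried unchanged to log-scale
    (the median and the scale differ by a multiplicative constant).
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    scale = median / math.log(2) ** (1.0 / shape)
    se = None
    if ci is not None:
        lo, hi = ci
        if not 0 < lo <= median <= hi:
            raise ValueError("CI must be positive and bracket the median")
        se = (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)
    return WeibullFit(shape, scale, se, "median_only")


def weibull_from_landmarks(landmarks: Mapping[float, float]) -> WeibullFit:
    """Fit (shape, scale) to landmark survival probabilities.

    Uses the complementary log-log linearization
    ln(-ln S(t)) = k ln t - k ln lambda, solved by least squares; with
    exactly two landmarks the fit is exact.
    """
    pts = [(t, s) for t, s in landmarks.items()]
    for t, s in pts:
        if not 0.0 < s < 1.0:
            raise ValueError(f"landmark survival at t={t} must be in (0,1)")
        if t <= 0:
            raise ValueError("landmark times must be positive")
    if len(pts) < 2:
        raise ValueError("need at least 2 landmarks to identify the shape")
    t = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    yy = np.log(-np.log(s))
    X = np.column_stack([np.log(t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
    k, c = float(coef[0]), float(coef[1])
    if k <= 0:
        raise ValueError("landmarks imply a non-increasing hazard order; "
                         "no valid Weibull fit")
    lam = math.exp(-c / k)
    return WeibullFit(k, lam, None, "landmarks")


def scale_from_single_landmark(t: float, s: float, shape: float) -> float:
    """Closed-form scale given one landmark and an externally supplied shape."""
    if not 0.0 < s < 1.0:
        raise ValueError("landmark survival must be in (0,1)")
    return t / (-math.log(s)) ** (1.0 / shape)


def hr_between(fit_a: WeibullFit, fit_b: WeibullFit,
               common_shape: float = 1.0, label: str = "") -> HrEstimate:
    """Hazard ratio of arm a relative to arm b at a shared Weibull shape.

    Under proportional hazards with common shape k, HR = (scale_b/scale_a)^k;
    medians re-anchor each fit at the common shape, so for k = 1 this is the
    inverse ratio of medians.  SEs of log-scale combine in quadrature scaled
    by k; if neither fit has an SE the estimate is returned with se flagged
    unavailable (None).
    """
    if common_shape <= 0:
        raise ValueError("common_shape must be positive")
    k = common_shape
    med_a, med_b = fit_a.median, fit_b.median
    scale_a = med_a / math.log(2) ** (1.0 / k)
    scale_b = med_b / math.log(2) ** (1.0 / k)
    log_hr = k * (math.log(scale_b) - math.log(scale_a))
    ses = [s for s in (fit_a.se_log_scale, fit_b.se_log_scale)
           if s is not None]
    se = k * math.sqrt(sum(s**2 for s in ses)) if ses else None
    return HrEstimate(log_hr, se, label)


def pool_log_hr(
    estimates: Sequence[HrEstimate],
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    tau_fixed: float | None = None,
) -> dict:
    """Bayesian random-effects pooling of log-hazard-ratios.

    Model: log_hr_i ~ N(delta_i, se_i^2), delta_i ~ N(mu, tau^2); returns the
    pooled HR exp(mu) with its equal-tailed 95% interval plus the underlying
    :class:`~immunometa.bayes_meta.MetaResult`.
    """
    usable = [e for e in estimates if e.se_log_hr is not None]
    if not usable:
        raise ValueError("no estimate carries a standard error")
    y = np.array([e.log_hr for e in usable])
    se = np.array([e.se_log_hr for e in usable])
    res: MetaResult = fit_normal_random_effects(y, se, prior, mcmc,
                                                tau_fixed=tau_fixed)
    hr_draws = np.exp(res.mu)
    flat = hr_draws.reshape(-1)
    return {
        "pooled_hr": float(np.median(flat)),
        "lower": float(np.quantile(flat, 0.025)),
        "upper": float(np.quantile(flat, 0.975)),
        "log_hr": res.summaries["mu"],
        "tau": res.summaries["tau"],
        "result": res,
        "n_pooled": len(usable),
    }
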