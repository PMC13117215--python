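"""Shared domain types, cohort table I/O, exact binomial intervals, count
reconstruction, and chained-equation imputation.

The patient-level unit is a cohort table: one row per patient, a fixed column
schema (:data:`PATIENT_FIELDS`), missing cells carried as NA with an explicit
boolean mask.  Study-level summaries (per-study enrolments, response counts,
rates, medians) are carried as :class:`StudySummary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = [
    "TUMOR_TYPES",
    "REGIMENS",
    "PATIENT_FIELDS",
    "StudySummary",
    "Cohort",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "counts_from_rate",
    "binom_interval",
    "impute_chained",
]

TUMOR_TYPES = ("melanoma", "dmmr_msih", "pan_solid", "gastric_gej", "tnbc")
REGIMENS = ("mono", "oxa_cape", "irinotecan", "gem_cis")
LINES = ("first", "second_plus")
MELANOMA_SUBTYPES = ("cutaneous", "acral", "mucosal", "other")
NLR_CHANGE = ("decrease", "stable", "increase")
MMR_MSI = ("dmmr_msih", "pmmr_mss")
RESPONSES = ("CR", "PR", "SD", "PD")
SEXES = ("M", "F")
ECOG = ("0", "1")
PDL1_CLONES = ("c22C3", "c28_8", "SAB028", "TPS_other")

# Column -> kind. Kinds: id, enum:<vocab>, flag (0/1), months (float >= 0).
_ENUM_VOCAB = {
    "tumor_type": TUMOR_TYPES,
    "melanoma_subtype": MELANOMA_SUBTYPES,
    "regimen": REGIMENS,
    "line": LINES,
    "sex": SEXES,
    "ecog": ECOG,
    "nlr_change": NLR_CHANGE,
    "mmr_msi": MMR_MSI,
    "response": RESPONSES,
}

FLAG_FIELDS = (
    "age_ge65",
    "pdl1_cps_pos",
    "kmt2d_mut",
    "nlr_baseline_ge4",
    "tmb_high",
    "eotaxin_high",
    "mcp1_high",
    "vegf_high",
    "thyroid_dysfunction_baseline",
    "irae_ge3",
    "pfs_event",
    "os_event",
)
MONTH_FIELDS = ("pfs_months", "os_months")

PATIENT_FIELDS = (
    "patient_id",
    "study_id",
    "tumor_type",
    "melanoma_subtype",
    "regimen",
    "line",
    "age_ge65",
    "sex",
    "ecog",
    "pdl1_cps_pos",
    "kmt2d_mut",
    "nlr_baseline_ge4",
    "nlr_change",
    "mmr_msi",
    "tmb_high",
    "eotaxin_high",
    "mcp1_high",
    "vegf_high",
    "thyroid_dysfunction_baseline",
    "response",
    "irae_ge3",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
)


@dataclass(frozen=True)
class StudySummary:
    """Per-study summary row: the unit of meta-analysis."""

    study_id: str
    tumor_type: str
    regimen: str
    line: str
    n_enrolled: int
    n_responders: int
    orr: float
    trae_ge3_rate: float
    irae_ge3_rate: float | None = None
    median_pfs_months: float | None = None
    pfs_ci: tuple[float, float] | None = None
    median_os_months: float | None = None
    os_ci: tuple[float, float] | None = None
    landmark_os: Mapping[float, float] | None = None
    pdl1_clone: str | None = None

    def __post_init__(self) -> None:
        if self.n_enrolled <= 0:
            raise ValueError("n_enrolled must be positive")
        if not 0 <= self.n_responders <= self.n_enrolled:
            raise ValueError("n_responders must lie in [0, n_enrolled]")
        if self.tumor_type not in TUMOR_TYPES:
            raise ValueError(f"unknown tumor_type {self.tumor_type!r}")
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        for name in ("orr", "trae_ge3_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1]")
        for pt, ci in (
            (self.median_pfs_months, self.pfs_ci),
            (self.median_os_months, self.os_ci),
        ):
            if ci is not None and pt is not None and not ci[0] <= pt <= ci[1]:
                raise ValueError("CI must bracket the point estimate")


class CohortParseError(ValueError):
    """Raised when a cohort file contains an invalid cell or duplicate id."""


@dataclass
class Cohort:
    """Patient-level table plus its missingness mask.

    ``table`` uses pandas nullable dtypes ("string" for enums/ids, "Int64"
    for 0/1 flags, "Float64" for month-valued columns); ``mask`` is True
    wherever the cell is missing.
    """

    table: pd.DataFrame
    mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.table.isna()

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "Cohort":
        return Cohort(self.table.copy(), self.mask.copy())

    def missing_fraction(self) -> pd.Series:
        return self.mask.mean()


def _empty_frame() -> pd.DataFrame:
    data = {}
    for col in PATIENT_FIELDS:
        if col in FLAG_FIELDS:
            data[col] = pd.Series(dtype="Int64")
        elif col in MONTH_FIELDS:
            data[col] = pd.Series(dtype="Float64")
        else:
            data[col] = pd.Series(dtype="string")
    return pd.DataFrame(data)


def validate_cohort_frame(df: pd.DataFrame) -> None:
    """Check schema, enum vocabulary, flag domain, and id uniqueness."""
    missing_cols = [c for c in PATIENT_FIELDS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"missing columns: {missing_cols}")
    ids = df["patient_id"].dropna()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise CohortParseError(f"duplicate patient_id: {dup.iloc[0]!r}")
    for col, vocab in _ENUM_VOCAB.items():
        bad = df[col].dropna()[~df[col].dropna().isin(vocab)]
        if len(bad):
            row = bad.index[0]
            raise CohortParseError(
                f"unknown token {bad.iloc[0]!r} in column {col!r}, row {row}"
            )
    for col in FLAG_FIELDS:
        vals = df[col].dropna()
        bad = vals[~vals.isin([0, 1])]
        if len(bad):
            raise CohortParseError(
                f"flag column {col!r} contains {bad.iloc[0]!r} at row {bad.index[0]}"
            )
    for col in MONTH_FIELDS:
        vals = df[col].dropna()
        if (vals < 0).any():
            row = vals[vals < 0].index[0]
            raise CohortParseError(f"negative time in {col!r} at row {row}")


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in PATIENT_FIELDS:
        s = df[col]
        if col in FLAG_FIELDS:
            try:
                out[col] = s.astype("Float64").astype("Int64")
            except (ValueError, TypeError) as exc:
                raise CohortParseError(f"non-integer value in flag column {col!r}: {exc}")
        elif col in MONTH_FIELDS:
            try:
                out[col] = s.astype("Float64")
            except (ValueError, TypeError) as exc:
                raise CohortParseError(f"non-numeric value in column {col!r}: {exc}")
        else:
            out[col] = s.astype("string")
    return pd.DataFrame(out)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (empty cells = missing) and validate it."""
    df = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    if df.empty and list(df.columns) == []:
        raise CohortParseError("file has no header row")
    df = _coerce_types(df) if len(df) else _empty_frame()
    validate_cohort_frame(df)
    return Cohort(df)


def write_cohort(path, cohort: Cohort) -> None:
    """Write a cohort to CSV; missing cells become empty fields."""
    validate_cohort_frame(cohort.table)
    cohort.table.to_csv(path, index=False)


def counts_from_rate(rate: float, n: int) -> int:
    """Reconstruct the integer count behind a printed rate.

    Returns the k in 0..n minimizing |k - rate*n|, ties rounded half up,
    so 0.806 * 31 = 24.986 -> 25.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    k = math.floor(rate * n + 0.5)
    return min(max(k, 0), n)


def binom_interval(
    x: int, n: int, level: float = 0.95, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Exact or Bayesian equal-tailed binomial interval for x successes of n.

    ``clopper_pearson`` is the exact beta-quantile construction (lower = 0 at
    x = 0, upper = 1 at x = n); ``jeffreys`` and ``uniform_posterior`` are
    equal-tailed posterior intervals under Beta(1/2,1/2) and Beta(1,1).
    """
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = 1.0 - level
    if method == "clopper_pearson":
        lo = 0.0 if x == 0 else float(beta_dist.ppf(a / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(beta_dist.ppf(1 - a / 2, x + 1, n - x))
    elif method == "jeffreys":
        # boundary convention (Brown-Cai-DasGupta): pin the empty-tail side
        lo = 0.0 if x == 0 else float(beta_dist.ppf(a / 2, x + 0.5,
                                                    n - x + 0.5))
        hi = 1.0 if x == n else float(beta_dist.ppf(1 - a / 2, x + 0.5,
                                                    n - x + 0.5))
    elif method == "uniform_posterior":
        lo = 0.0 if x == 0 else float(beta_dist.ppf(a / 2, x + 1, n - x + 1))
        hi = 1.0 if x == n else float(beta_dist.ppf(1 - a / 2, x + 1,
                                                    n - x + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return lo, hi


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------

def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1e-3,
                    max_iter: int = 50) -> np.ndarray:
    """Newton-Raphson fit of a ridge-penalized logistic model (intercept in X)."""
    p = X.shape[1]
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-6)
        grad = X.T @ (y - mu) - pen @ beta
        hess = (X * w[:, None]).T @ X + pen + 1e-8 * np.eye(p)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for col in predictors:
        s = df[col]
        if col in FLAG_FIELDS:
            cols.append(s.astype(float).to_numpy())
        elif col in MONTH_FIELDS:
            v = s.astype(float).to_numpy()
            sd = np.nanstd(v)
            cols.append((v - np.nanmean(v)) / (sd if sd > 0 else 1.0))
        else:
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:
                cols.append((s == lev).astype(float).to_numpy())
    return np.column_stack(cols)


def impute_chained(
    cohort: Cohort,
    target_fields: Sequence[str],
    n_cycles: int = 5,
    seed: int = 0,
) -> Cohort:
    """Single-imputation chained equations on the listed fields.

    Binary (flag) fields are drawn from a ridge-logistic conditional model,
    multi-level categoricals from normalized one-vs-rest logistic
    probabilities, and continuous fields from a linear-Gaussian model.
    Observed cells are never modified; a fixed seed reproduces the output.
    """
    rng = np.random.default_rng(seed)
    df = cohort.table.copy()
    mask = cohort.mask

    targets = [f for f in target_fields if mask[f].any()]
    for f in target_fields:
        if f not in PATIENT_FIELDS:
            raise ValueError(f"unknown field {f!r}")
        if mask[f].all():
            raise ValueError(f"field {f!r} is entirely missing; nothing to fit on")
        if mask[f].mean() > 0.5:
            raise ValueError(f"field {f!r} exceeds 50% missingness")
    if not targets:
        return cohort.copy()

    predictors_all = [
        c for c in PATIENT_FIELDS
        if c not in ("patient_id",) and not mask[c].all()
    ]

    # Initialize holes with draws from the observed marginal.
    for f in targets:
        obs = df.loc[~mask[f], f]
        idx = df.index[mask[f]]
        draw = rng.choice(obs.to_numpy(), size=len(idx), replace=True)
        df.loc[idx, f] = pd.array(draw, dtype=df[f].dtype)

    for _ in range(n_cycles):
        for f in targets:
            miss = mask[f].to_numpy()
            # predictors: fully observed columns plus other (initialized) targets
            preds = [c for c in predictors_all
                     if c != f and (not mask[c].any() or c in targets)]
            X = _design_matrix(df, preds)
            if f in FLAG_FIELDS:
                y = df[f].astype(float).to_numpy()
                b = _ridge_logistic(X[~miss], y[~miss])
                p = 1.0 / (1.0 + np.exp(-np.clip(X[miss] @ b, -30, 30)))
                new = (rng.random(miss.sum()) < p).astype(int)
                df.loc[df.index[miss], f] = pd.array(new, dtype="Int64")
            elif f in MONTH_FIELDS:
                y = df[f].astype(float).to_numpy()
                XtX = X[~miss].T @ X[~miss] + 1e-6 * np.eye(X.shape[1])
                bhat = np.linalg.solve(XtX, X[~miss].T @ y[~miss])
                resid = y[~miss] - X[~miss] @ bhat
                sigma = float(np.std(resid)) if len(resid) > 1 else 0.0
                new = X[miss] @ bhat + rng.normal(0, sigma, miss.sum())
                df.loc[df.index[miss], f] = pd.array(
                    np.maximum(new, 0.0), dtype="Float64")
            else:
                levels = sorted(df.loc[~miss, f].dropna().unique())
                if len(levels) == 1:
                    df.loc[df.index[miss], f] = levels[0]
                    continue
                probs = np.zeros((int(miss.sum()), len(levels)))
                for j, lev in enumerate(levels):
                    y = (df[f] == lev).astype(float).to_numpy()
                    b = _ridge_logistic(X[~miss], y[~miss])
                    probs[:, j] = 1.0 / (
                        1.0 + np.exp(-np.clip(X[miss] @ b, -30, 30)))
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random(len(probs))
                choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                new = [levels[c] for c in choice]
                df.loc[df.index[miss], f] = pd.array(new, dtype="string")

    out_mask = mask.copy()
    out_mask[targets] = False
    return Cohort(df, out_mask)
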