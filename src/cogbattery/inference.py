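"""Statistical layer: outlier rules, covariate-adjusted linear models,
effect sizes, Holm correction and JZS Bayes factors.

Every cognitive outcome is analyzed with ordinary least squares: infection
status (never positive = 0, previously positive = 1) as the focal predictor
and age (mean-centered within the analysis sample), gender (female = 0,
male = 1), education (no post-secondary = 0), depressiveness (PHQ-9),
anxiety (GAD-7) and stress (PSQ-20) as covariates. Standardized
coefficients are beta = b * SD(x) / SD(y) on the listwise-complete sample;
p values are two-tailed.

Bayes factors follow the Jeffreys–Zellner–Siow setup: for t tests, a Cauchy
prior on the standardized effect with scale r = sqrt(2)/2 integrated
against the noncentral-t likelihood; for regression terms, the ratio of two
Zellner–Siow mixture-of-g marginal likelihoods (full vs reduced model),
each a one-dimensional integral over g evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

DEFAULT_COVARIATES = (
    "age",
    "gender_male",
    "education",
    "phq9_total",
    "gad7_total",
    "psq20_total",
)

JZS_CAUCHY_SCALE = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# Outlier rules
# ---------------------------------------------------------------------------


def tukey_outlier_mask(values) -> np.ndarray:
    """Boolean mask of values beyond 1.5 IQR outside [Q1, Q3].

    Quartiles use the default linear-interpolation definition. Requires at
    least four finite values; an all-identical vector yields an empty mask.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("tukey_outlier_mask requires >= 4 finite values")
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = np.zeros(x.shape, dtype=bool)
    mask[finite] = (x[finite] < lo) | (x[finite] > hi)
    return mask


def groupwise_2sd_mask(values, group_labels) -> np.ndarray:
    """Mask of values more than two SDs from their own group's mean.

    Means and SDs are computed once per group (no iteration); each group
    needs at least three finite values. NaNs are never flagged.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if x.shape != g.shape:
        raise ValueError("values and group_labels must align")
    mask = np.zeros(x.shape, dtype=bool)
    for label in pd.unique(g):
        sel = (g == label) & np.isfinite(x)
        if sel.sum() < 3:
            raise ValueError(f"group {label!r} has fewer than 3 finite values")
        m, s = x[sel].mean(), x[sel].std(ddof=1)
        if s > 0:
            mask[sel] = np.abs(x[sel] - m) > 2.0 * s
    return mask


# ---------------------------------------------------------------------------
# Model specification and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One covariate-adjusted regression, in the battery's table layout.

    ``focal`` is the term whose Bayes factor is reported. Terms are column
    names of the analysis table; ``a:b`` denotes a product term. Any term
    named ``age`` (also inside products) is mean-centered within the
    analysis sample. ``subsample`` restricts rows before fitting.
    """

    outcome: str
    focal: Optional[str] = "infection"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    extra_terms: tuple[str, ...] = ()
    subsample: str = "all"  # all | previously_positive | recovered_or_never
    log_outcome: bool = False
    name: str = ""

    def terms(self) -> list[str]:
        out = [] if self.focal is None else [self.focal]
        out += [t for t in self.covariates if t not in out]
        out += [t for t in self.extra_terms if t not in out]
        return out


@dataclass(frozen=True)
class TermStats:
    b: float
    se: float
    beta: float
    t: float
    p: float


@dataclass(frozen=True)
class ModelResult:
    spec: ModelSpec
    terms: dict[str, TermStats]
    intercept: TermStats
    r2: float
    adj_r2: float
    f: float
    df_model: int
    df_resid: int
    p_model: float
    n_used: int
    bf10_focal: float = float("nan")


class CollinearityError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def _apply_subsample(data: pd.DataFrame, subsample: str) -> pd.DataFrame:
    if subsample == "all":
        return data
    if subsample == "previously_positive":
        return data[data["infection"] == 1]
    if subsample == "recovered_or_never":
        rec = data.get("recovered")
        if rec is None:
            raise KeyError("subsample 'recovered_or_never' needs a 'recovered' column")
        rec = rec.astype("boolean").fillna(False)
        return data[((data["infection"] == 0) | rec).to_numpy(dtype=bool)]
    raise ValueError(f"unknown subsample {subsample!r}")


def _base_columns(terms: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for t in terms:
        for c in t.split(":"):
            if c not in cols:
                cols.append(c)
    return cols


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Listwise-complete design matrix (with intercept), response and names."""
    data = _apply_subsample(data, spec.subsample)
    terms = spec.terms()
    base = _base_columns(terms)
    missing = [c for c in [spec.outcome] + base if c not in data.columns]
    if missing:
        raise KeyError(f"missing analysis column(s): {', '.join(missing)}")
    sub = data[[spec.outcome] + base].apply(pd.to_numeric, errors="coerce")
    sub = sub.dropna()
    if spec.log_outcome:
        pos = sub[spec.outcome] > 0
        sub = sub[pos]
    n = len(sub)
    if n <= len(terms) + 1:
        raise InsufficientDataError(
            f"{n} complete rows for {len(terms)} terms; model not estimable"
        )
    work = sub.copy()
    if "age" in work.columns:
        work["age"] = work["age"] - work["age"].mean()
    cols = []
    for t in terms:
        parts = t.split(":")
        v = work[parts[0]].to_numpy(dtype=float)
        for p in parts[1:]:
            v = v * work[p].to_numpy(dtype=float)
        cols.append(v)
    X = np.column_stack([np.ones(n)] + cols)
    y = work[spec.outcome].to_numpy(dtype=float)
    if spec.log_outcome:
        y = np.log(y)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a culprit: a term whose removal restores full rank
        for j, t in enumerate(terms, start=1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                raise CollinearityError(f"design is rank deficient; term {t!r} is collinear")
        raise CollinearityError("design is rank deficient")
    return X, y, terms, sub


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec,
                     compute_bf: bool = True) -> ModelResult:
    """Ordinary least squares with standardized betas and the focal-term BF10."""
    import statsmodels.api as sm

    X, y, terms, _ = build_design(data, spec)
    res = sm.OLS(y, X).fit()
    sd_y = float(np.std(y, ddof=1))
    stats: dict[str, TermStats] = {}
    for j, t in enumerate(terms, start=1):
        sd_x = float(np.std(X[:, j], ddof=1))
        beta = float(res.params[j] * sd_x / sd_y) if sd_y > 0 else float("nan")
        stats[t] = TermStats(
            b=float(res.params[j]),
            se=float(res.bse[j]),
            beta=beta,
            t=float(res.tvalues[j]),
            p=float(res.pvalues[j]),
        )
    intercept = TermStats(
        b=float(res.params[0]), se=float(res.bse[0]), beta=float("nan"),
        t=float(res.tvalues[0]), p=float(res.pvalues[0]),
    )
    bf = float("nan")
    if compute_bf and spec.focal is not None:
        bf = bf10_regression_term(data, spec, spec.focal)
    return ModelResult(
        spec=spec,
        terms=stats,
        intercept=intercept,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_model=float(res.f_pvalue),
        n_used=int(res.nobs),
        bf10_focal=bf,
    )


# ---------------------------------------------------------------------------
# Multiple testing, effect size, t tests
# ---------------------------------------------------------------------------


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must be finite and in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mults = (m - np.arange(m)) * p[order]  # (m, m-1, ..., 1) * ascending p
    adj_sorted = np.minimum(np.maximum.accumulate(mults), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def cohens_d_pooled(m1: float, sd1: float, n1: int,
                    m2: float, sd2: float, n2: int) -> float:
    """Cohen's d with the pooled standard deviation."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("both standard deviations are zero; d undefined")
    return (m1 - m2) / math.sqrt(sp2)


def welch_or_student_ttest(x, y, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t test (pooled variance by default), two-tailed.

    Returns (t, df, p). The battery's auxiliary group comparisons use the
    Student (pooled) form, matching integer df = n1 + n2 - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = float(len(x) + len(y) - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------


def bf10_ttest(t: float, n1: int, n2: Optional[int] = None,
               cauchy_scale: float = JZS_CAUCHY_SCALE) -> float:
    """JZS Bayes factor for a t statistic (two-sample when n2 is given).

    Integrates the noncentral-t likelihood against a Cauchy(0, r) prior on
    the standardized effect size and divides by the central-t likelihood.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n2 is None:
        n_eff, df = float(n1), float(n1 - 1)
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("group sizes must be >= 2")
        n_eff = n1 * n2 / (n1 + n2)
        df = float(n1 + n2 - 2)
    root_n = math.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, df, delta * root_n) * sps.cauchy.pdf(
            delta, scale=cauchy_scale
        )

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    den = sps.t.pdf(t, df)
    if not np.isfinite(num) or den <= 0:
        raise ValueError("non-finite Bayes factor integrand")
    return num / den


def _log_jzs_marginal_ratio(n: int, p: int, r2: float,
                            r_scale: float = JZS_CAUCHY_SCALE) -> float:
    """log BF of a p-covariate linear model against the intercept-only model.

    Zellner–Siow mixture of g priors: g ~ InverseGamma(1/2, r^2 n / 2),
    BF = E_g[(1+g)^((n-1-p)/2) (1 + g (1-R^2))^(-(n-1)/2)].
    """
    if p == 0:
        return 0.0
    a = r_scale**2 * n / 2.0

    def log_f(u: float) -> float:
        g = math.exp(u)
        lp = (
            0.5 * math.log(a)
            - math.lgamma(0.5)
            - 1.5 * u
            - a / g
            + u  # Jacobian of g = exp(u)
        )
        return (
            lp
            + 0.5 * (n - 1 - p) * math.log1p(g)
            - 0.5 * (n - 1) * math.log1p(g * (1.0 - r2))
        )

    us = np.linspace(-12.0, 20.0, 64)
    u0 = float(us[np.argmax([log_f(u) for u in us])])
    shift = log_f(u0)

    def f(u: float) -> float:
        return math.exp(log_f(u) - shift)

    val, _ = integrate.quad(f, -30.0, 40.0, limit=300)
    return shift + math.log(val)


def bf10_regression_term(data: pd.DataFrame, spec: ModelSpec,
                         focal_term: str) -> float:
    """BF10 of the full regression against the model without ``focal_term``.

    Both models are fit on the same listwise-complete rows of the full
    design; the reduced model is nested by construction. Dropping an empty
    focal term compares the model with itself (BF = 1).
    """
    if focal_term is not None and focal_term not in spec.terms():
        raise ValueError(f"focal term {focal_term!r} not in model terms")
    X, y, terms, _ = build_design(data, spec)
    n = len(y)

    def r2_of(Xm: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0

    log_full = _log_jzs_marginal_ratio(n, len(terms), r2_of(X))
    if focal_term is None:
        return 1.0
    j = terms.index(focal_term) + 1
    Xr = np.delete(X, j, axis=1)
    log_red = _log_jzs_marginal_ratio(n, len(terms) - 1, r2_of(Xr))
    return math.exp(log_full - log_red)


BF_BANDS = (
    (10.0, "strong_H1"),
    (3.0, "moderate_H1"),
    (1.0, "anecdotal_H1"),
    (1.0 / 3.0, "anecdotal_H0"),
    (1.0 / 10.0, "moderate_H0"),
)


def interpret_bf(bf10: float) -> str:
    """Evidence band of a BF10 under the conventional classification.

    > 10 strong H1; 3–10 moderate H1; 1–3 anecdotal H1; exactly 1
    equivocal; 1/3–1 anecdotal H0; 1/10–1/3 moderate H0; < 1/10 strong H0.
    """
    if not (np.isfinite(bf10) and bf10 > 0):
        raise ValueError("bf10 must be a positive finite number")
    if bf10 > 10:
        return "strong_H1"
    if bf10 > 3:
        return "moderate_H1"
    if bf10 > 1:
        return "anecdotal_H1"
    if bf10 == 1:
        return "equivocal"
    if bf10 >= 1.0 / 3.0:
        return "anecdotal_H0"
    if bf10 >= 1.0 / 10.0:
        return "moderate_H0"
    return "strong_H0"


# ---------------------------------------------------------------------------
# Null-cohort calibration
# ---------------------------------------------------------------------------


def simulate_null_analysis_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Participant-level analysis table with no infection effect.

    Covariates mimic the cohort layer's marginals (age, gender, education
    imbalance, correlated questionnaire totals); the outcome is pure noise,
    so rejections of the focal infection term are type-I errors.
    """
    infection = (rng.random(n) < 0.65).astype(int)
    age = np.clip(rng.normal(44, 14.5, n), 18, 90)
    gender_male = (rng.random(n) < 0.28).astype(int)
    education = (rng.random(n) < 0.44 - 0.10 * infection).astype(int)
    mood = rng.normal(0, 1, n) + 0.3 * infection
    phq9 = np.clip(6.1 + 4.5 * mood + rng.normal(0, 2.0, n), 0, 27)
    gad7 = np.clip(5.7 + 3.5 * mood + rng.normal(0, 2.0, n), 0, 21)
    psq20 = np.clip(40 + 17 * mood + rng.normal(0, 10.0, n), 0, 100)
    outcome = rng.normal(0.3, 0.18, n)  # independent of everything
    return pd.DataFrame(
        {
            "infection": infection,
            "age": age,
            "gender_male": gender_male,
            "education": education,
            "phq9_total": phq9,
            "gad7_total": gad7,
            "psq20_total": psq20,
            "outcome": outcome,
        }
    )


def focal_power_simulation(
    n1: int = 76,
    n2: int = 62,
    effect: float = -0.08,
    outcome_sd: float = 0.18,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical power of the focal infection test at given group sizes.

    Participant-level simulation: the outcome is baseline + effect for the
    infected group plus Gaussian noise, analyzed with the full covariate
    model. Defaults mirror the memory task's group sizes and spread.
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec(outcome="outcome", focal="infection")
    hits = 0
    for _ in range(n_reps):
        data = simulate_null_analysis_table(n1 + n2, rng)
        data["infection"] = np.repeat([1, 0], [n1, n2])
        data["outcome"] = 0.32 + effect * data["infection"] + rng.normal(
            0, outcome_sd, n1 + n2
        )
        res = fit_linear_model(data, spec, compute_bf=False)
        if res.terms["infection"].p < 0.05:
            hits += 1
    return hits / n_reps


def null_rejection_rate(
    n_reps: int = 10_000,
    n: int = 150,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the focal infection test on null cohorts."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(outcome="outcome", focal="infection")
    hits = 0
    for _ in range(n_reps):
        data = simulate_null_analysis_table(n, rng)
        res = fit_linear_model(data, spec, compute_bf=False)
        if res.terms["infection"].p < alpha:
            hits += 1
    return hits / n_reps
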