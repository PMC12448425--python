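"""Statistical battery for cohort tables.

Univariable screen (Shapiro-Wilk, Spearman, Mann-Whitney, Kruskal-Wallis)
and two multivariable models per shape metric: a Huber-weighted robust
linear regression for the continuous EOR outcome and a logistic
regression for the binary focal-deficit outcome.

The robust and logistic fitters are implemented here (IRLS / Newton) so
they can be cross-checked against independent references in the tests;
the rank tests delegate to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import (
    ConvergenceError,
    GliomaShapeError,
    RankDeficiencyError,
    SchemaError,
    SeparationError,
)

__all__ = [
    "UnivariableResult",
    "GroupSummary",
    "ModelSpec",
    "RegressionFit",
    "shapiro_screen",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "huber_regression",
    "huber_fit",
    "logistic_regression",
    "logistic_fit",
    "run_univariable_battery",
    "run_multivariable_models",
    "battery_frame",
]

log = logging.getLogger("gliomashape")

ALPHA = 0.05
HUBER_TUNING = 1.345  # 95% Gaussian efficiency
LOCATION_REFERENCE = "central_deep"


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class UnivariableResult:
    test: str
    statistic: float
    p_value: float
    n: int
    variable: str = ""
    shape_metric: str = ""
    groups: dict[str, GroupSummary] | None = None
    alpha: float = ALPHA

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise GliomaShapeError(f"p-value out of [0, 1]: {self.p_value}")
        if self.groups:
            if sum(g.n for g in self.groups.values()) != self.n:
                raise GliomaShapeError("group sizes must sum to analyzed n")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ModelSpec:
    """Which multivariable model to fit.

    EOR models adjust for age, preoperative volume, eloquence, and lobar
    location; deficit models for age, preoperative volume, and eloquence.
    """

    outcome: str  # "eor" | "focal_deficit"
    shape_predictor: str  # "csa" | "si"
    location_reference: str = LOCATION_REFERENCE

    def __post_init__(self):
        if self.outcome not in ("eor", "focal_deficit"):
            raise GliomaShapeError(f"unknown outcome {self.outcome!r}")
        if self.shape_predictor not in ("csa", "si"):
            raise GliomaShapeError(f"unknown shape predictor {self.shape_predictor!r}")

    @property
    def includes_location(self) -> bool:
        return self.outcome == "eor"


@dataclass(frozen=True)
class RegressionFit:
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n_used: int
    converged: bool
    n_iter: int
    scale: float | None = None
    model: str = ""

    def __post_init__(self):
        if not (np.all(self.ci_low <= self.coef + 1e-12) and np.all(self.coef <= self.ci_high + 1e-12)):
            raise GliomaShapeError("confidence intervals must bracket coefficients")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p_value": float(self.p_values[i]),
        }


# --------------------------------------------------------------------------
# univariable tests
# --------------------------------------------------------------------------


def _summary(values: np.ndarray) -> GroupSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(n=len(values), median=float(med), q1=float(q1), q3=float(q3))


def shapiro_screen(values, alpha: float = ALPHA) -> UnivariableResult:
    """Shapiro-Wilk normality test; ``significant`` flags non-normality."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise GliomaShapeError("shapiro_screen needs n >= 3")
    if np.ptp(x) == 0:
        raise GliomaShapeError("shapiro_screen is undefined for constant input")
    res = stats.shapiro(x)
    return UnivariableResult(
        test="shapiro_wilk", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=len(x), alpha=alpha,
    )


def spearman(x, y, alpha: float = ALPHA) -> UnivariableResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise GliomaShapeError("x and y must have equal length")
    if len(x) < 3:
        raise GliomaShapeError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GliomaShapeError("spearman is undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return UnivariableResult(
        test="spearman", statistic=float(rho), p_value=float(p), n=len(x), alpha=alpha
    )


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b, alpha: float = ALPHA) -> UnivariableResult:
    """Mann-Whitney U (count of a > b pairs + half-ties), two-sided p.

    Exact enumeration when both groups have n <= 8 and there are no ties,
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise GliomaShapeError("mann_whitney needs both groups nonempty")
    exact = len(a) <= 8 and len(b) <= 8 and not _has_ties(np.concatenate([a, b]))
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return UnivariableResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(a) + len(b),
        groups={"a": _summary(a), "b": _summary(b)},
        alpha=alpha,
    )


def kruskal_wallis(groups, alpha: float = ALPHA) -> UnivariableResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise GliomaShapeError("kruskal_wallis needs >= 2 nonempty groups")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all pooled values identical: H = 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return UnivariableResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n=sum(len(g) for g in arrays),
        groups={str(i): _summary(g) for i, g in enumerate(arrays)},
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# regression fitters
# --------------------------------------------------------------------------


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns whose removal does not drop the rank are aliased
        aliased = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(names[j])
        raise RankDeficiencyError(aliased or names)


def _mad_scale(resid: np.ndarray) -> float:
    """Normalized median absolute deviation about zero."""
    return float(np.median(np.abs(resid)) / _Z75)


_Z75 = stats.norm.ppf(0.75)
_Z975 = stats.norm.ppf(0.975)


def huber_regression(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tuning: float = HUBER_TUNING,
    tol: float = 1e-8,
    max_iter: int = 200,
    model: str = "huber",
) -> RegressionFit:
    """Huber-weighted robust linear regression by IRLS.

    Weights ``min(1, c / |r/s|)`` with tuning constant ``c`` on residuals
    standardized by the normalized-MAD scale ``s`` (re-estimated each
    iteration).  Converges when the largest coefficient change is below
    ``tol``.  Standard errors use the Huber-corrected asymptotic
    covariance (the "H1" sandwich).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if n <= p:
        raise GliomaShapeError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, names)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    scale = 0.0
    it = 0
    change = np.inf
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = _mad_scale(resid)
        if scale < 1e-12:  # (near-)perfect fit
            converged = True
            break
        u = resid / scale
        w = np.minimum(1.0, tuning / np.maximum(np.abs(u), 1e-300))
        wx = X * w[:, None]
        beta_new = np.linalg.solve(wx.T @ X, wx.T @ y)
        change = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(it, change)

    if scale < 1e-12:
        se = np.zeros(p)
    else:
        u = (y - X @ beta) / scale
        psi = np.clip(u, -tuning, tuning)  # Huber psi
        psi_deriv = (np.abs(u) <= tuning).astype(float)
        m1 = psi_deriv.mean()
        k = 1.0 + (p / n) * psi_deriv.var() / m1**2  # Huber small-sample correction
        s2 = (scale**2) * np.sum(psi**2) / (n - p)
        cov = k**2 * s2 / m1**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 0.0)
    return RegressionFit(
        terms=tuple(names),
        coef=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p_values=pvals,
        n_used=n,
        converged=True,
        n_iter=it,
        scale=scale,
        model=model,
    )


def logistic_regression(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    model: str = "logistic",
) -> RegressionFit:
    """Maximum-likelihood logistic regression (Newton-Raphson with step
    halving), Wald 95% intervals.

    Raises :class:`SeparationError` when complete or quasi-complete
    separation drives coefficients to diverge, and verifies that the
    log-likelihood never decreases across accepted steps.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise GliomaShapeError("outcome must be coded 0/1")
    if len(classes) < 2:
        raise GliomaShapeError("outcome has a single class; nothing to fit")
    _check_rank(X, names)

    def loglik(beta):
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    beta = np.zeros(p)
    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        hess = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular Hessian; complete or quasi-complete separation suspected"
            )
        # step halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        change = float(np.max(np.abs(factor * step)))
        ll = max(ll, ll_new)
        if np.max(np.abs(X @ beta)) > 100.0:
            raise SeparationError(
                "diverging linear predictor (|eta| > 100); complete or "
                "quasi-complete separation in the design"
            )
        if change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(it, change)

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return RegressionFit(
        terms=tuple(names),
        coef=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p_values=2.0 * stats.norm.sf(np.abs(z)),
        n_used=n,
        converged=True,
        n_iter=it,
        scale=None,
        model=model,
    )


# --------------------------------------------------------------------------
# cohort-level drivers
# --------------------------------------------------------------------------

_SHAPE_COLS = {"csa": "csa_cm2", "si": "si"}
_OUTCOME_COLS = {"eor": "eor", "focal_deficit": "focal_deficit"}


def _require_columns(cohort: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise SchemaError([f"missing column {c!r}" for c in missing])


def build_design(
    spec: ModelSpec, cohort: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix, outcome vector, and term names for one model.

    Biopsy-only rows and rows with a missing outcome are excluded
    (complete case).  Lobar location is dummy-coded against the reference
    category for EOR models.
    """
    outcome_col = _OUTCOME_COLS[spec.outcome]
    shape_col = _SHAPE_COLS[spec.shape_predictor]
    needed = ["age", "pre_volume_cm3", shape_col, "eloquent", "biopsy_only", outcome_col]
    if spec.includes_location:
        needed.append("location")
    _require_columns(cohort, needed)

    df = cohort.loc[(cohort["biopsy_only"] == 0) & cohort[outcome_col].notna()].copy()
    cols = {
        "intercept": np.ones(len(df)),
        "age": df["age"].to_numpy(float),
        "pre_volume": df["pre_volume_cm3"].to_numpy(float),
        spec.shape_predictor: df[shape_col].to_numpy(float),
        "eloquent": df["eloquent"].to_numpy(float),
    }
    if spec.includes_location:
        levels = sorted(set(df["location"]) - {spec.location_reference})
        for lev in levels:
            cols[f"location[{lev}]"] = (df["location"] == lev).to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    y = df[outcome_col].to_numpy(float)
    return X, y, names


def huber_fit(spec: ModelSpec, cohort: pd.DataFrame, tuning: float = HUBER_TUNING) -> RegressionFit:
    """Fit the robust EOR model described by ``spec`` on a cohort table."""
    if spec.outcome != "eor":
        raise GliomaShapeError("huber_fit handles the continuous eor outcome")
    X, y, names = build_design(spec, cohort)
    fit = huber_regression(X, y, names, tuning=tuning, model=f"huber:eor~{spec.shape_predictor}")
    return fit


def logistic_fit(spec: ModelSpec, cohort: pd.DataFrame) -> RegressionFit:
    """Fit the logistic focal-deficit model described by ``spec``."""
    if spec.outcome != "focal_deficit":
        raise GliomaShapeError("logistic_fit handles the binary focal_deficit outcome")
    X, y, names = build_design(spec, cohort)
    return logistic_regression(
        X, y, names, model=f"logistic:focal_deficit~{spec.shape_predictor}"
    )


def run_univariable_battery(
    cohort: pd.DataFrame, alpha: float = ALPHA
) -> list[UnivariableResult]:
    """Shape-metric association screen.

    One result per (variable, metric) cell: Spearman for age and EOR,
    Mann-Whitney for sex, histological subtype, and focal deficits,
    Kruskal-Wallis for lobar location.  Biopsy-only rows are excluded
    from EOR and deficit tests; subtype tests use only analyzed tumors.
    """
    _require_columns(cohort, COHORT_REQUIRED)
    results: list[UnivariableResult] = []
    resection = cohort[cohort["biopsy_only"] == 0]

    def _cell(variable, metric, fn, groups=None):
        try:
            results.append(_tag(fn(), variable, metric, groups))
        except GliomaShapeError as exc:
            log.info("skipping univariable cell (%s, %s): %s", variable, metric, exc)

    for metric, col in _SHAPE_COLS.items():
        _cell("age", metric, lambda: spearman(cohort["age"], cohort[col], alpha))
        sub = resection[resection["eor"].notna()]
        _cell("eor", metric, lambda: spearman(sub["eor"], sub[col], alpha))

        male = cohort.loc[cohort["sex"] == "male", col]
        female = cohort.loc[cohort["sex"] == "female", col]
        _cell("sex", metric, lambda: mann_whitney(male, female, alpha),
              {"male": male, "female": female})

        astro = cohort.loc[cohort["diagnosis"] == "astrocytoma", col]
        oligo = cohort.loc[cohort["diagnosis"] == "oligodendroglioma", col]
        _cell("histological_subtype", metric, lambda: mann_whitney(astro, oligo, alpha),
              {"astrocytoma": astro, "oligodendroglioma": oligo})

        dsub = resection[resection["focal_deficit"].notna()]
        yes = dsub.loc[dsub["focal_deficit"] == 1.0, col]
        no = dsub.loc[dsub["focal_deficit"] == 0.0, col]
        _cell("focal_deficits", metric, lambda: mann_whitney(yes, no, alpha),
              {"yes": yes, "no": no})

        present = [
            (loc, cohort.loc[cohort["location"] == loc, col])
            for loc in cohort["location"].unique()
        ]
        present = [(loc, v) for loc, v in present if len(v)]
        _cell("location", metric,
              lambda: kruskal_wallis([v for _, v in present], alpha), dict(present))
    return results


COHORT_REQUIRED = [
    "age", "sex", "location", "diagnosis", "csa_cm2", "si",
    "biopsy_only", "eor", "focal_deficit",
]


def _tag(
    r: UnivariableResult, variable: str, metric: str, groups: dict | None = None
) -> UnivariableResult:
    g = (
        {name: _summary(np.asarray(v, dtype=float)) for name, v in groups.items()}
        if groups is not None
        else r.groups
    )
    return UnivariableResult(
        test=r.test, statistic=r.statistic, p_value=r.p_value, n=r.n,
        variable=variable, shape_metric=metric, groups=g, alpha=r.alpha,
    )


def battery_frame(results: list[UnivariableResult]) -> pd.DataFrame:
    """Flatten battery results into a tidy frame (one row per group or,
    for correlation tests, per result)."""
    rows = []
    for r in results:
        base = {
            "variable": r.variable,
            "shape_metric": r.shape_metric,
            "test": r.test,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "significant": r.significant,
            "n": r.n,
        }
        if r.groups:
            for name, g in r.groups.items():
                rows.append(
                    {**base, "group": name, "group_n": g.n,
                     "median": g.median, "q1": g.q1, "q3": g.q3}
                )
        else:
            rows.append({**base, "group": "", "group_n": np.nan,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
    return pd.DataFrame(rows)


def run_multivariable_models(
    cohort: pd.DataFrame,
    tuning: float = HUBER_TUNING,
    location_reference: str = LOCATION_REFERENCE,
) -> dict[tuple[str, str], RegressionFit]:
    """The four adjusted models: EOR ~ {CSA, SI} (robust linear) and
    focal_deficit ~ {CSA, SI} (logistic)."""
    fits: dict[tuple[str, str], RegressionFit] = {}
    for metric in ("csa", "si"):
        spec = ModelSpec("eor", metric, location_reference)
        fits[("eor", metric)] = huber_fit(spec, cohort, tuning=tuning)
        spec = ModelSpec("focal_deficit", metric, location_reference)
        fits[("focal_deficit", metric)] = logistic_fit(spec, cohort)
    return fits
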