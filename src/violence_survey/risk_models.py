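"""Multivariable logistic odds-ratio models with multiple imputation.

The risk-factor analysis is a maximum-likelihood logistic regression of each
directly elicited binary outcome on a set of pandemic-related and general
predictors, reported as odds ratios with normal-theory confidence intervals.
Partner mental health is observed only through the respondent's assessment
and is sometimes missing; it is completed by multiple imputation with chained
equations (Bayesian normal-linear conditional draws), after which estimates
are pooled over the m completed datasets with Rubin's rules:

    point     = mean of per-imputation estimates
    variance  = W + (1 + 1/m) * B

with W the mean within-imputation variance and B the between-imputation
variance. Reference categories are carried through as odds ratio 1.0 with no
interval, mirroring conventional risk-factor tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "PredictorSpec",
    "TermResult",
    "RiskModelResult",
    "RiskProfile",
    "ProfilePrediction",
    "build_design",
    "chained_imputation",
    "fit_logistic_risk_model",
    "predicted_probability",
    "rubin_pool",
    "women_predictor_spec",
    "child_predictor_spec",
]

_SEPARATION_SE = 1e2  # a pooled SE beyond this on the log-odds scale is flagged


@dataclass(frozen=True)
class Term:
    """One model term: a binary flag, a per-unit continuous predictor, or a
    categorical variable expanded to dummies against a reference level."""

    name: str
    kind: str = "binary"  # "binary" | "continuous" | "categorical"
    column: str | None = None
    reference: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical term {self.name!r} needs a reference level")
        if self.column is None:
            object.__setattr__(self, "column", self.name)


@dataclass(frozen=True)
class PredictorSpec:
    terms: tuple[Term, ...]
    reference_rows: tuple[str, ...] = ()  # extra rows rendered as OR 1.0 (-)

    def design_columns(self, df: pd.DataFrame) -> list[str]:
        return list(build_design(df, self).columns)


def build_design(df: pd.DataFrame, spec: PredictorSpec) -> pd.DataFrame:
    """Numeric design matrix (no intercept) with one column per estimated term.

    Categorical terms become ``column:level`` dummies, reference level
    omitted. Rows with missing source values propagate NaN so callers can
    apply listwise deletion.
    """
    cols = {}
    for t in spec.terms:
        if t.kind == "categorical":
            series = df[t.column]
            levels = t.levels or tuple(sorted(series.dropna().unique()))
            if t.reference not in levels:
                raise ValueError(f"reference {t.reference!r} not a level of {t.column!r}")
            for lev in levels:
                if lev == t.reference:
                    continue
                d = (series == lev).astype(float)
                d[series.isna()] = np.nan
                cols[f"{t.column}:{lev}"] = d
        else:
            cols[t.name] = pd.to_numeric(df[t.column], errors="coerce")
    out = pd.DataFrame(cols, index=df.index)
    return out


def predictor_column(df: pd.DataFrame, key: str) -> np.ndarray:
    """Resolve a design-column key (``col`` or ``col:level``) to values."""
    if ":" in key:
        col, level = key.split(":", 1)
        s = df[col]
        vals = (s == level).astype(float).to_numpy()
        vals[s.isna().to_numpy()] = np.nan
        return vals
    return pd.to_numeric(df[key], errors="coerce").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# default predictor specifications

def _pandemic_terms() -> list[Term]:
    return [
        Term("quarantine"),
        Term("financial_worries"),
        Term("own_reduced_work"),
        Term("partner_reduced_work"),
        Term("poor_mental_health"),
        Term("partner_poor_mental_health"),
        Term("childcare_hours", kind="continuous"),
        Term("children_lt10"),
        Term("children_ge10"),
    ]


def _general_terms() -> list[Term]:
    return [
        Term("age", kind="continuous"),
        Term(
            "education",
            kind="categorical",
            reference="middle_or_less",
            levels=("middle_or_less", "lower_secondary", "higher_secondary"),
        ),
        Term(
            "income",
            kind="categorical",
            reference="lt2000",
            levels=("lt2000", "2000_4000", "gt4000", "no_answer"),
        ),
        Term("employed"),
        Term("partner_employed"),
        Term("key_worker"),
        Term("household_size", kind="continuous"),
        Term("cohabiting"),
    ]


def women_predictor_spec(full: bool = True) -> PredictorSpec:
    """Risk-factor specification for the women's outcomes.

    ``full=True`` is the complete table specification (pandemic block plus
    sociodemographics); ``full=False`` keeps the pandemic block and age only.
    """
    terms = _pandemic_terms() + (_general_terms() if full else [Term("age", kind="continuous")])
    return PredictorSpec(terms=tuple(terms))


def child_predictor_spec(full: bool = True) -> PredictorSpec:
    """Specification for the child corporal-punishment model.

    Estimated within households with children; "children >= 10 only" is the
    implicit reference group, so the children_ge10 flag is not estimated and
    is rendered as a reference row.
    """
    terms = [t for t in _pandemic_terms() if t.name != "children_ge10"]
    terms += _general_terms() if full else [Term("age", kind="continuous")]
    return PredictorSpec(terms=tuple(terms), reference_rows=("children_ge10",))


# ---------------------------------------------------------------------------
# chained imputation

def chained_imputation(
    df: pd.DataFrame,
    target_vars: Sequence[str],
    m: int = 10,
    seed: int = 0,
    n_cycles: int = 10,
    predictors: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """m completed copies of ``df`` with continuous ``target_vars`` imputed.

    Each chain cycles ``n_cycles`` times over the targets; at every step the
    target is regressed on the predictor set (plus the other targets' current
    values) over its originally observed rows, the error variance and
    coefficients are drawn from their approximate posterior, and missing
    entries are replaced by posterior-predictive draws. With no missing data
    the result is m unmodified copies. Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    targets = list(target_vars)
    for t in targets:
        if t not in df.columns:
            raise KeyError(f"imputation target {t!r} not in dataset")
        if df[t].notna().sum() == 0:
            raise ValueError(f"imputation target {t!r} is entirely missing")

    miss = {t: df[t].isna().to_numpy() for t in targets}
    if not any(mask.any() for mask in miss.values()):
        return [df.copy() for _ in range(m)]

    if predictors is None:
        predictors = [
            c
            for c in df.columns
            if c not in targets
            and c != "id"
            and not c.startswith("latent_true_")
            and pd.api.types.is_numeric_dtype(df[c])
            and df[c].notna().all()
            and df[c].nunique() > 1
        ]
    pred_mat = df[list(predictors)].to_numpy(dtype=float)

    completed = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chain]))
        vals = {t: df[t].to_numpy(dtype=float).copy() for t in targets}
        for t in targets:  # initial fill: random draws from observed values
            obs = vals[t][~miss[t]]
            vals[t][miss[t]] = rng.choice(obs, size=miss[t].sum(), replace=True)

        for _ in range(n_cycles):
            for t in targets:
                others = [vals[u] for u in targets if u != t]
                x = np.column_stack([np.ones(len(df)), pred_mat] + [o[:, None] for o in others])
                y, mask = vals[t], miss[t]
                xo, yo = x[~mask], y[~mask]
                beta_hat, *_ = np.linalg.lstsq(xo, yo, rcond=None)
                resid = yo - xo @ beta_hat
                dof = max(xo.shape[0] - xo.shape[1], 1)
                sigma2 = float(resid @ resid) / rng.chisquare(dof)
                xtx_inv = np.linalg.pinv(xo.T @ xo)
                cov = 0.5 * sigma2 * (xtx_inv + xtx_inv.T)  # symmetrize
                beta = rng.multivariate_normal(beta_hat, cov, method="svd")
                y[mask] = x[mask] @ beta + rng.normal(0.0, np.sqrt(sigma2), mask.sum())

        out = df.copy()
        for t in targets:
            out[t] = vals[t]
        completed.append(out)
    return completed


# ---------------------------------------------------------------------------
# model fitting and pooling

@dataclass(frozen=True)
class TermResult:
    name: str
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    reference: bool = False
    separation: bool = False
    coef: float | None = None
    se: float | None = None

    def format(self) -> str:
        if self.reference:
            return "1.0 (–)"
        if self.separation:
            return f"{self.odds_ratio:.2f} (separation; CI unbounded)"
        return f"{self.odds_ratio:.2f} ({self.ci_low:.2f} to {self.ci_high:.2f})"


@dataclass(frozen=True)
class RiskModelResult:
    outcome: str
    n_analytic: int
    m_imputations: int
    terms: tuple[TermResult, ...]
    columns: tuple[str, ...]        # design columns, intercept first ("const")
    params: tuple[float, ...]       # pooled log-odds coefficients
    cov: tuple[tuple[float, ...], ...]  # pooled covariance (Rubin total)
    design_means: tuple[float, ...]     # analytic-sample means, const included
    within_var: tuple[float, ...]
    between_var: tuple[float, ...]
    ci_level: float = 0.95

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def rubin_pool(points, variances) -> tuple[float, float, float, float]:
    """Pool per-imputation scalar estimates: (point, total var, W, B)."""
    q = np.asarray(points, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or q.size == 0:
        raise ValueError("points and variances must be equal-length 1-D arrays")
    m = q.size
    point = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    total = w + (1.0 + 1.0 / m) * b if m > 1 else w
    return point, total, w, b


def _fit_one(y: np.ndarray, x: np.ndarray):
    """One ML logistic fit; falls back to BFGS under (near-)separation."""
    model = sm.Logit(y, x)
    try:
        res = model.fit(disp=0, maxiter=100)
        if np.isfinite(res.params).all() and np.isfinite(res.bse).all():
            return res.params, res.cov_params()
    except (PerfectSeparationError, np.linalg.LinAlgError):
        pass
    res = model.fit(disp=0, method="bfgs", maxiter=500)
    cov = res.cov_params()
    params = np.asarray(res.params, dtype=float)
    cov = np.where(np.isfinite(cov), cov, _SEPARATION_SE**2)
    return params, cov


def fit_logistic_risk_model(
    completed_datasets,
    outcome: str,
    predictor_spec: PredictorSpec,
    ci_level: float = 0.95,
) -> RiskModelResult:
    """Fit the logistic model on each completed dataset and pool with Rubin's rules.

    ``completed_datasets`` may be a single DataFrame (complete-case fit) or
    the list returned by :func:`chained_imputation`. Rows with a missing
    outcome or predictor are dropped listwise. Terms whose pooled standard
    error explodes (separation) are flagged rather than raising.
    """
    if isinstance(completed_datasets, pd.DataFrame):
        completed_datasets = [completed_datasets]
    m = len(completed_datasets)
    if m == 0:
        raise ValueError("need at least one dataset")

    all_params, all_covs, all_means, n_analytic = [], [], [], None
    columns = None
    for df in completed_datasets:
        design = build_design(df, predictor_spec)
        y = pd.to_numeric(df[outcome], errors="coerce")
        keep = y.notna() & design.notna().all(axis=1)
        yv = y[keep].to_numpy(dtype=float)
        xv = design[keep].to_numpy(dtype=float)
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError(f"outcome {outcome!r} is not binary")
        if yv.min() == yv.max():
            raise ValueError(f"outcome {outcome!r} has a single class in the analytic sample")
        columns = ("const", *design.columns)
        xc = np.column_stack([np.ones(len(xv)), xv])
        params, cov = _fit_one(yv, xc)
        all_params.append(params)
        all_covs.append(np.asarray(cov))
        all_means.append(xc.mean(axis=0))
        n_analytic = len(yv) if n_analytic is None else min(n_analytic, len(yv))

    q = np.vstack(all_params)
    point = q.mean(axis=0)
    w_mat = np.mean(all_covs, axis=0)
    if m > 1:
        dev = q - point
        b_mat = dev.T @ dev / (m - 1)
        t_mat = w_mat + (1.0 + 1.0 / m) * b_mat
    else:
        b_mat = np.zeros_like(w_mat)
        t_mat = w_mat
    se = np.sqrt(np.diag(t_mat))
    z = norm.ppf(1 - (1 - ci_level) / 2)

    results = []
    for j, name in enumerate(columns):
        if name == "const":
            continue
        sep = (not np.isfinite(se[j])) or se[j] >= _SEPARATION_SE or abs(point[j]) > 30
        results.append(
            TermResult(
                name=name,
                odds_ratio=float(np.exp(point[j])),
                ci_low=None if sep else float(np.exp(point[j] - z * se[j])),
                ci_high=None if sep else float(np.exp(point[j] + z * se[j])),
                separation=bool(sep),
                coef=float(point[j]),
                se=float(se[j]),
            )
        )
        if sep:
            logger.warning("%s: term %s flagged for separation (se=%.3g)", outcome, name, se[j])
    for name in predictor_spec.reference_rows:
        results.append(TermResult(name=name, odds_ratio=1.0, ci_low=None, ci_high=None, reference=True))

    return RiskModelResult(
        outcome=outcome,
        n_analytic=int(n_analytic),
        m_imputations=m,
        terms=tuple(results),
        columns=tuple(columns),
        params=tuple(float(v) for v in point),
        cov=tuple(tuple(float(v) for v in row) for row in t_mat),
        design_means=tuple(float(v) for v in np.mean(all_means, axis=0)),
        within_var=tuple(float(v) for v in np.diag(w_mat)),
        between_var=tuple(float(v) for v in np.diag(b_mat)),
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# risk profiles and predicted probabilities

@dataclass(frozen=True)
class RiskProfile:
    """Named covariate settings; unprofiled covariates stay at analytic means."""

    name: str
    settings: tuple[tuple[str, float], ...]

    @classmethod
    def from_dict(cls, name: str, settings: dict) -> "RiskProfile":
        return cls(name=name, settings=tuple((k, float(v)) for k, v in settings.items()))


@dataclass(frozen=True)
class ProfilePrediction:
    """Predicted probability (percent) at a covariate profile, delta-method CI."""

    profile: str
    outcome: str
    probability: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def format(self) -> str:
        from ._formatting import fmt_pct

        return (
            f"{fmt_pct(self.probability)}% "
            f"({fmt_pct(self.ci_low)} to {fmt_pct(self.ci_high)})"
        )


def predicted_probability(
    model: RiskModelResult, profile: RiskProfile, ci_level: float = 0.95
) -> ProfilePrediction:
    """Inverse-logit of the linear predictor at a profile.

    Profiled predictors are set to their stated values; every other design
    column is held at its analytic-sample mean. The interval is the delta
    method applied on the linear-predictor scale and mapped through the
    inverse logit, so it is always inside (0, 100).
    """
    x = np.asarray(model.design_means, dtype=float).copy()
    cols = list(model.columns)
    for key, val in profile.settings:
        if key not in cols or key == "const":
            raise KeyError(f"profile names unknown model term {key!r}")
        x[cols.index(key)] = float(val)
    beta = np.asarray(model.params)
    cov = np.asarray(model.cov)
    lp = float(x @ beta)
    var = float(x @ cov @ x)
    z = norm.ppf(1 - (1 - ci_level) / 2)
    half = z * np.sqrt(var)
    return ProfilePrediction(
        profile=profile.name,
        outcome=model.outcome,
        probability=100.0 * float(expit(lp)),
        ci_low=100.0 * float(expit(lp - half)),
        ci_high=100.0 * float(expit(lp + half)),
        ci_level=ci_level,
    )
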