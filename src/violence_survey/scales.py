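"""Likert-item batteries: PCA-weighted scores, internal consistency, quintile flags.

Multi-item instruments (depression/anxiety screeners, financial-concern
batteries, social-desirability scales) are summarized as continuous scores by
projecting standardized items onto the first principal component of their
correlation matrix; internal consistency is reported as Cronbach's alpha.
Risk-factor dummies are "top quintile of the score" flags. The module also
computes the disclosure gradient: reported prevalence of a sensitive outcome
across social-desirability quintiles, with a trend statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "ScaleScore",
    "GradientResult",
    "cronbach_alpha",
    "pca_scale_score",
    "top_quintile_flag",
    "disclosure_gradient",
]


@dataclass(frozen=True)
class ScaleScore:
    name: str
    loadings: tuple[float, ...]
    scores: np.ndarray          # zero mean over complete cases; NaN if all items missing
    alpha: float
    top_quintile: np.ndarray    # 1.0 / 0.0, NaN where score missing
    partial: np.ndarray         # True where score used an incomplete item set


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, complete-case.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with n-1 variances. Requires >= 2 items and >= 3 complete rows.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / total_var))


def pca_scale_score(item_matrix, name: str = "", alpha: float | None = None) -> ScaleScore:
    """First-principal-component score of standardized items.

    Items are z-scored with complete-case means and SDs; loadings are the
    leading eigenvector of the item correlation matrix, sign-fixed so that a
    positive loading sum points "more symptoms/worry -> higher score".
    Respondents with some (not all) items missing get a score from the
    available items, rescaled by the inverse of the available squared-loading
    mass, and are flagged ``partial``.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    missing = np.isnan(x)
    complete = ~missing.any(axis=1)
    if complete.sum() < 3:
        raise ValueError("need at least 3 complete rows to estimate loadings")

    mu = x[complete].mean(axis=0)
    sd = x[complete].std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("an item has zero variance; cannot standardize")
    z = (x - mu) / sd

    if k == 1:
        v = np.array([1.0])
    else:
        corr = np.corrcoef(z[complete], rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        v = eigvecs[:, -1]
        if v.sum() < 0:
            v = -v
        v = v / np.linalg.norm(v)

    scores = np.full(n, np.nan)
    scores[complete] = z[complete] @ v
    partial = ~complete & ~missing.all(axis=1)
    for i in np.flatnonzero(partial):
        avail = ~missing[i]
        w = v[avail]
        scores[i] = (z[i, avail] @ w) / (w @ w)  # rescale to full-loading mass

    # center on complete cases (projection of centered z is mean zero there)
    scores = scores - np.nanmean(scores[complete])

    a = cronbach_alpha(x) if (alpha is None and k >= 2) else (alpha if alpha is not None else 1.0)
    flags = top_quintile_flag(scores)
    return ScaleScore(
        name=name,
        loadings=tuple(float(w) for w in v),
        scores=scores,
        alpha=float(a),
        top_quintile=flags,
        partial=partial,
    )


def top_quintile_flag(scores) -> np.ndarray:
    """Flag scores at or above the empirical 80th percentile.

    Ties at the cutpoint are all flagged. Missing scores yield NaN flags.
    All-equal scores are an error: quintiles are undefined.
    """
    s = np.asarray(scores, dtype=float)
    valid = ~np.isnan(s)
    if valid.sum() < 5:
        raise ValueError("need at least 5 non-missing scores")
    vals = s[valid]
    if np.all(vals == vals[0]):
        raise ValueError("all scores equal; quintiles undefined")
    cut = np.percentile(vals, 80)
    out = np.full(s.shape, np.nan)
    out[valid] = (s[valid] >= cut).astype(float)
    return out


def quintile_index(scores) -> np.ndarray:
    """1-based quintile index (1 = lowest fifth), NaN-preserving."""
    s = np.asarray(scores, dtype=float)
    valid = ~np.isnan(s)
    if valid.sum() < 5:
        raise ValueError("need at least 5 non-missing scores")
    cuts = np.percentile(s[valid], [20, 40, 60, 80])
    out = np.full(s.shape, np.nan)
    # ties at a cutpoint go to the upper quintile, consistent with top_quintile_flag
    out[valid] = 1.0 + np.searchsorted(cuts, s[valid], side="right")
    return out


@dataclass(frozen=True)
class GradientResult:
    """Reported prevalence by social-desirability quintile plus a trend slope.

    ``slope`` is the least-squares slope of the individual binary report on
    the quintile index (a Cochran-Armitage-style linear trend); negative
    values mean disclosure falls as social-desirability sensitivity rises.
    Rates are percentages.
    """

    outcome: str
    rates: tuple[float, ...]
    counts: tuple[int, ...]
    slope: float
    pvalue: float


def disclosure_gradient(
    df: pd.DataFrame,
    outcome: str,
    sd_scores=None,
    sd_item_prefix: str = "social_desirability_item",
) -> GradientResult:
    """Reported prevalence of ``direct_{outcome}`` by social-desirability quintile."""
    report = df[f"direct_{outcome}"]
    if sd_scores is None:
        item_cols = [c for c in df.columns if c.startswith(sd_item_prefix)]
        if not item_cols:
            raise KeyError("no social-desirability items or scores provided")
        sd_scores = pca_scale_score(df[item_cols].to_numpy(), "social_desirability").scores
    s = np.asarray(sd_scores, dtype=float)
    y = report.to_numpy(dtype=float)
    ok = ~np.isnan(s) & ~np.isnan(y)
    q = quintile_index(np.where(ok, s, np.nan))

    rates, counts = [], []
    for j in range(1, 6):
        in_q = ok & (q == j)
        if in_q.sum() == 0:
            raise ValueError(f"social-desirability quintile {j} is empty")
        rates.append(100.0 * float(y[in_q].mean()))
        counts.append(int(in_q.sum()))
    if np.all(y[ok] == y[ok][0]):
        slope, pvalue = 0.0, 1.0  # degenerate: constant reports, flat trend
    else:
        fit = linregress(q[ok], y[ok])
        slope, pvalue = float(fit.slope), float(fit.pvalue)
    return GradientResult(
        outcome=outcome,
        rates=tuple(rates),
        counts=tuple(counts),
        slope=slope,
        pvalue=pvalue,
    )
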