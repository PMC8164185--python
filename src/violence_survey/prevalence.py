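"""Direct-elicitation prevalence estimation with binomial confidence intervals.

The workhorse is the normal-approximation (Wald) interval
``p ± z * sqrt(p (1 - p) / n)`` reported on the percent scale. Wald intervals
are the convention in descriptive survey tables of this kind; alternative
intervals (Wilson, Clopper-Pearson) are available behind a flag but are never
the default because they do not reproduce the usual printed tables from
(count, denominator) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from ._formatting import fmt_pct

__all__ = ["PrevalenceEstimate", "estimate_prevalence", "prevalence_table", "descriptive_table"]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A binomial proportion on the percent scale with its confidence interval.

    ``proportion`` is always ``100 * count / denominator``; the interval is
    symmetric about it (Wald) unless an alternative ``method`` was requested.
    ``clipped`` records whether the interval was truncated into [0, 100].
    """

    count: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    name: str = ""
    method: str = "wald"
    clipped: bool = False

    def format(self, ndigits: int = 2) -> str:
        """Render as e.g. ``'3.09 (2.54 to 3.64)'``, half-up to 2 decimals."""
        return (
            f"{fmt_pct(self.proportion, ndigits)} "
            f"({fmt_pct(self.ci_low, ndigits)} to {fmt_pct(self.ci_high, ndigits)})"
        )


def estimate_prevalence(
    count: int,
    denominator: int,
    ci_level: float = 0.95,
    *,
    name: str = "",
    method: str = "wald",
    clip: bool = False,
) -> PrevalenceEstimate:
    """Estimate a prevalence (in percent) from a count and a denominator.

    Parameters
    ----------
    count, denominator
        Number of positive respondents and number of respondents asked.
    ci_level
        Two-sided confidence level, default 0.95 (z = 1.959964).
    method
        ``"wald"`` (default), ``"wilson"`` or ``"clopper-pearson"``.
    clip
        If True, truncate the interval into [0, 100] and flag the estimate.
        Off by default: a Wald lower bound below zero is reported as such.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")

    p = count / denominator
    if method == "wald":
        z = norm.ppf(1 - (1 - ci_level) / 2)
        half = z * np.sqrt(p * (1 - p) / denominator)
        lo, hi = p - half, p + half
    elif method in ("wilson", "clopper-pearson"):
        sm_name = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
        lo, hi = proportion_confint(count, denominator, alpha=1 - ci_level, method=sm_name)
    else:
        raise ValueError(f"unknown interval method {method!r}")

    clipped = False
    if clip:
        lo_c, hi_c = max(lo, 0.0), min(hi, 1.0)
        clipped = (lo_c, hi_c) != (lo, hi)
        lo, hi = lo_c, hi_c

    return PrevalenceEstimate(
        count=int(count),
        denominator=int(denominator),
        proportion=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        ci_level=ci_level,
        name=name,
        method=method,
        clipped=clipped,
    )


def _resolve_mask(df: pd.DataFrame, subgroup_rule) -> np.ndarray:
    if subgroup_rule is None:
        return np.ones(len(df), dtype=bool)
    if callable(subgroup_rule):
        mask = np.asarray(subgroup_rule(df), dtype=bool)
    else:
        mask = np.asarray(subgroup_rule, dtype=bool)
    if mask.shape != (len(df),):
        raise ValueError("subgroup rule must yield one boolean per row")
    return mask


def prevalence_table(
    df: pd.DataFrame,
    outcomes: Sequence[str],
    subgroup_rule: Callable[[pd.DataFrame], Iterable[bool]] | None = None,
    ci_level: float = 0.95,
    **kwargs,
) -> list[PrevalenceEstimate]:
    """One prevalence estimate per binary outcome column.

    Denominators respect both missingness (rows with a missing outcome are
    excluded from that outcome's denominator) and an optional subgroup rule
    (e.g. households with children). An outcome observed for nobody is an
    error rather than a silent zero.
    """
    mask = _resolve_mask(df, subgroup_rule)
    out = []
    for col in outcomes:
        if col not in df.columns:
            raise KeyError(f"outcome column {col!r} not in dataset")
        vals = df.loc[mask, col]
        vals = vals[vals.notna()]
        if len(vals) == 0:
            raise ValueError(f"outcome {col!r} has no observed values in the subgroup")
        arr = vals.to_numpy(dtype=float)
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"outcome {col!r} is not binary")
        out.append(
            estimate_prevalence(int(arr.sum()), len(arr), ci_level, name=col, **kwargs)
        )
    return out


def descriptive_table(
    df: pd.DataFrame,
    binary_vars: Sequence[str] = (),
    categorical_vars: Sequence[str] = (),
    ci_level: float = 0.95,
) -> list[PrevalenceEstimate]:
    """Sample-characteristics shares ("No. women (%)" style rows).

    Binary variables yield one row; categorical variables yield one row per
    observed level, named ``var=level``.
    """
    rows = list(prevalence_table(df, binary_vars, ci_level=ci_level))
    for col in categorical_vars:
        if col not in df.columns:
            raise KeyError(f"variable {col!r} not in dataset")
        vals = df[col][df[col].notna()]
        if len(vals) == 0:
            raise ValueError(f"variable {col!r} has no observed values")
        for level, n in vals.value_counts().sort_index().items():
            est = estimate_prevalence(int(n), len(vals), ci_level, name=f"{col}={level}")
            rows.append(est)
    return rows
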