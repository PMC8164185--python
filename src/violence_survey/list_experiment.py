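"""Item-count (list-experiment) estimators for stigmatized outcomes.

In a single list experiment respondents are randomized to a reference list of
innocuous statements or to the same list plus one sensitive statement, and
report only *how many* statements apply. The prevalence of the sensitive item
is the difference in mean counts between arms.

In the double design every respondent answers two lists and carries the
sensitive item on exactly one of them (which one depends on the randomized
arm). Within each arm the per-respondent difference

    D_i = (count on the sensitive-bearing list) - (count on the control list)

has expectation equal to the sensitive-item prevalence, and averaging the two
arm means halves the variance relative to a single design of the same size
because shared respondent-level variation differences out.

Estimates are reported on the percent scale and confidence intervals are
never truncated at zero: a negative lower bound is informative about the
precision of the design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ListEstimate",
    "single_list_estimate",
    "double_list_estimate",
    "power_simulation",
]


@dataclass(frozen=True)
class ListEstimate:
    """Double-list difference-in-means estimate, percent scale."""

    outcome: str
    tau_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_arm_a: int
    n_arm_b: int
    per_list_estimates: tuple[float, float]
    ci_level: float = 0.95
    n_dropped: int = 0
    floor_ceiling_flag: bool = False

    def format(self, ndigits: int = 2) -> str:
        from ._formatting import fmt_pct

        lo = fmt_pct(self.ci_low, ndigits)
        if self.ci_low < 0:  # typography: unicode minus as in printed tables
            lo = "−" + lo.lstrip("-")
        return f"{fmt_pct(self.tau_hat, ndigits)} ({lo} to {fmt_pct(self.ci_high, ndigits)})"


def single_list_estimate(treatment_counts, control_counts) -> tuple[float, float]:
    """Difference in mean item counts between the sensitive-list and control arms.

    Returns ``(estimate, se)`` on the proportion (count) scale. The standard
    error is the unpooled two-sample formula ``sqrt(s_t^2/n_t + s_c^2/n_c)``
    with n-1 sample variances.
    """
    t = np.asarray(treatment_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both arms must be non-empty")
    est = t.mean() - c.mean()
    var_t = t.var(ddof=1) if t.size > 1 else 0.0
    var_c = c.var(ddof=1) if c.size > 1 else 0.0
    se = float(np.sqrt(var_t / t.size + var_c / c.size))
    return float(est), se


def double_list_estimate(
    df: pd.DataFrame,
    outcome: str,
    ci_level: float = 0.95,
    n_control_items: int = 4,
) -> ListEstimate:
    """Double-list estimator for ``outcome``.

    Expects columns ``{outcome}_arm`` (values "A"/"B"), ``{outcome}_list1``
    and ``{outcome}_list2``. Arm A carries the sensitive item on list 1, arm
    B on list 2. Respondents missing the arm or either count are dropped
    listwise for this outcome (with a logged count).

    The variance treats the two arms as independent samples and exploits the
    within-respondent pairing inside each arm:
    ``var = (var(D_A)/n_A + var(D_B)/n_B) / 4``.
    """
    cols = [f"{outcome}_arm", f"{outcome}_list1", f"{outcome}_list2"]
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"column {c!r} not in dataset")
    sub = df[cols].dropna()
    n_dropped = len(df) - len(sub)
    if n_dropped:
        logger.info("%s: dropped %d respondents with missing list data", outcome, n_dropped)

    arm = sub[cols[0]].astype(str).to_numpy()
    l1 = sub[cols[1]].to_numpy(dtype=float)
    l2 = sub[cols[2]].to_numpy(dtype=float)
    in_a, in_b = arm == "A", arm == "B"
    if not (in_a | in_b).all():
        raise ValueError("list arm must be 'A' or 'B'")
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("both randomization arms must be non-empty")

    d_a = l1[in_a] - l2[in_a]  # sensitive item on list 1 in arm A
    d_b = l2[in_b] - l1[in_b]  # sensitive item on list 2 in arm B
    tau = 0.5 * (d_a.mean() + d_b.mean())
    var = 0.25 * (d_a.var(ddof=1) / d_a.size + d_b.var(ddof=1) / d_b.size)
    se = float(np.sqrt(var))
    z = norm.ppf(1 - (1 - ci_level) / 2)

    # cross-arm single-list estimates; their average equals tau exactly
    per_list = (
        float(l1[in_a].mean() - l1[in_b].mean()),
        float(l2[in_b].mean() - l2[in_a].mean()),
    )

    flag = _floor_ceiling_check(outcome, l1, l2, in_a, in_b, n_control_items)

    return ListEstimate(
        outcome=outcome,
        tau_hat=100.0 * float(tau),
        se=100.0 * se,
        ci_low=100.0 * float(tau - z * se),
        ci_high=100.0 * float(tau + z * se),
        n_arm_a=int(in_a.sum()),
        n_arm_b=int(in_b.sum()),
        per_list_estimates=(100.0 * per_list[0], 100.0 * per_list[1]),
        ci_level=ci_level,
        n_dropped=int(n_dropped),
        floor_ceiling_flag=flag,
    )


def _floor_ceiling_check(outcome, l1, l2, in_a, in_b, n_control_items) -> bool:
    """Warn when >5% of respondents sit at a list's floor or ceiling.

    Piled-up counts at 0 or at the maximum undermine the design: respondents
    at the ceiling of a sensitive-bearing list are no longer protected, and
    floor/ceiling effects can bias the difference in means.
    """
    flagged = False
    for name, counts, ceiling in (
        ("list1", l1, n_control_items + 1.0),
        ("list2", l2, n_control_items + 1.0),
    ):
        share = float(np.mean((counts == 0) | (counts >= ceiling)))
        if share > 0.05:
            flagged = True
            warnings.warn(
                f"{outcome}/{name}: {share:.1%} of respondents at list floor/ceiling",
                stacklevel=3,
            )
    return flagged


def power_simulation(
    true_prevalence: float,
    n: int,
    reps: int = 500,
    *,
    control_item_probs=(0.2, 0.4, 0.6, 0.8),
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Monte-Carlo comparison of double vs single list designs at the same n.

    Simulates ``reps`` surveys of ``n`` respondents with the sensitive trait
    drawn Bernoulli(true_prevalence) and independent Bernoulli control items,
    then records the empirical standard error, mean CI width and rejection
    rate (two-sided test of tau = 0) of each design.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100 for stable summaries")
    if not 0 <= true_prevalence <= 1:
        raise ValueError("true_prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.asarray(control_item_probs, dtype=float)
    z = norm.ppf(1 - alpha / 2)

    res = {"double": {"est": [], "se": []}, "single": {"est": [], "se": []}}
    for _ in range(reps):
        truth = rng.random(n) < true_prevalence
        c1 = (rng.random((n, p.size)) < p).sum(axis=1).astype(float)
        c2 = (rng.random((n, p.size)) < p).sum(axis=1).astype(float)
        arm_a = rng.permutation(n) < n // 2

        # double design: everyone answers both lists
        l1 = c1 + np.where(arm_a, truth, 0)
        l2 = c2 + np.where(~arm_a, truth, 0)
        d_a = (l1 - l2)[arm_a]
        d_b = (l2 - l1)[~arm_a]
        tau = 0.5 * (d_a.mean() + d_b.mean())
        se = np.sqrt(0.25 * (d_a.var(ddof=1) / d_a.size + d_b.var(ddof=1) / d_b.size))
        res["double"]["est"].append(tau)
        res["double"]["se"].append(se)

        # single design: one list each, treatment arm sees the sensitive item
        counts = c1 + np.where(arm_a, truth, 0)
        est, se_s = single_list_estimate(counts[arm_a], counts[~arm_a])
        res["single"]["est"].append(est)
        res["single"]["se"].append(se_s)

    out = {}
    for design, d in res.items():
        est = np.asarray(d["est"])
        se = np.asarray(d["se"])
        out[design] = {
            "empirical_se": 100.0 * float(est.std(ddof=1)),
            "mean_model_se": 100.0 * float(se.mean()),
            "mean_ci_width": 100.0 * float((2 * z * se).mean()),
            "rejection_rate": float(np.mean(np.abs(est) > z * se)),
            "mean_estimate": 100.0 * float(est.mean()),
        }
    return out
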