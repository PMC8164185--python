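"""Optional figure helpers (the numbers, not the pixels, are the test surface)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .risk_models import ProfilePrediction
from .scales import GradientResult


def plot_disclosure_gradient(gradient: GradientResult, ax=None):
    """Bar chart of reported prevalence by social-desirability quintile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(range(1, 6), gradient.rates, color="#4878a8")
    ax.set_xlabel("Social-desirability quintile")
    ax.set_ylabel("Reported prevalence (%)")
    ax.set_title(f"{gradient.outcome}: trend slope {gradient.slope:+.4f}")
    return ax


def plot_profile_probabilities(predictions: list[ProfilePrediction], ax=None):
    """Point-and-interval plot of predicted probabilities per outcome/profile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * max(len(predictions), 4) + 1))
    labels = [f"{p.outcome.removeprefix('direct_')} [{p.profile}]" for p in predictions]
    y = range(len(predictions))
    probs = [p.probability for p in predictions]
    lo = [p.probability - p.ci_low for p in predictions]
    hi = [p.ci_high - p.probability for p in predictions]
    ax.errorbar(probs, y, xerr=[lo, hi], fmt="o", color="#a84848", capsize=3)
    ax.set_yticks(list(y), labels)
    ax.set_xlabel("Predicted probability (%)")
    ax.invert_yaxis()
    return ax
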