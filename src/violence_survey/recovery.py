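"""Monte-Carlo recovery studies: does the pipeline get known truths back?

Two study designs:

* :func:`list_recovery_study` — repeatedly simulate surveys whose latent
  sensitive-item prevalence is known, apply the double-list estimator, and
  summarize bias and interval width.
* :func:`or_coverage_study` — repeatedly simulate surveys whose latent
  outcomes follow a logistic model with known odds ratios, run the full
  imputation + pooled-logistic pipeline, and record how often each pooled
  95% interval covers its generating odds ratio.

Both are driven by the synthetic generator, so they characterize the whole
implementation, not just the estimators in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .list_experiment import double_list_estimate
from .risk_models import (
    PredictorSpec,
    chained_imputation,
    child_predictor_spec,
    fit_logistic_risk_model,
    women_predictor_spec,
)
from .scales import top_quintile_flag
from .synthetic_data import (
    FLAG_COLUMNS,
    GeneratorConfig,
    OutcomeSpec,
    ScaleSpec,
    default_covariate_marginals,
    generate_dataset,
    list_recovery_config,
)

__all__ = ["ListRecoveryResult", "list_recovery_study", "or_coverage_study", "or_recovery_config"]


@dataclass(frozen=True)
class ListRecoveryResult:
    truth: float                # percent
    n_respondents: int
    n_reps: int
    mean_estimate: float        # percent
    mc_se_of_mean: float        # percent
    empirical_se: float         # percent
    mean_ci_width: float        # percent
    estimates: tuple[float, ...]


def list_recovery_study(
    true_prevalence: float,
    n: int = 3818,
    reps: int = 1000,
    seed: int = 0,
    outcome: str = "sexual_violence",
) -> ListRecoveryResult:
    """Simulate ``reps`` double-list surveys and summarize the estimator.

    Each replicate draws a fresh survey from the generator (four Bernoulli
    control items per list, 1:1 arm randomization, i.i.d. latent truth) and
    applies :func:`double_list_estimate`. All quantities are in percent.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    ests, widths = [], []
    for ss in child_seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        cfg = list_recovery_config(outcome, true_prevalence, n, rep_seed)
        df = generate_dataset(cfg)
        est = double_list_estimate(df, outcome)
        ests.append(est.tau_hat)
        widths.append(est.ci_high - est.ci_low)
    ests_arr = np.asarray(ests)
    return ListRecoveryResult(
        truth=100.0 * true_prevalence,
        n_respondents=n,
        n_reps=reps,
        mean_estimate=float(ests_arr.mean()),
        mc_se_of_mean=float(ests_arr.std(ddof=1) / np.sqrt(reps)),
        empirical_se=float(ests_arr.std(ddof=1)),
        mean_ci_width=float(np.mean(widths)),
        estimates=tuple(float(e) for e in ests_arr),
    )


def or_recovery_config(n: int = 3818, seed: int = 0) -> GeneratorConfig:
    """Generator configuration for the odds-ratio coverage study.

    One women's outcome and one child outcome with table-style odds ratios on
    the pandemic-related block plus age; disclosure suppression is switched
    off so the analyzed reports equal the latent truth (non-differential
    under-reporting would attenuate every odds ratio and make coverage of the
    generating values the wrong yardstick). Missingness reproduces the
    analytic-sample attrition: partner mental health is imputable, childcare
    hours are dropped listwise.
    """
    women_ors = {
        "quarantine": 2.38,
        "financial_worries": 1.60,
        "own_reduced_work": 2.07,
        "partner_reduced_work": 1.07,
        "poor_mental_health": 3.41,
        "partner_poor_mental_health": 2.23,
        "childcare_hours": 1.07,
        "children_lt10": 2.48,
        "children_ge10": 1.36,
        "age": 0.97,
    }
    child_ors = {
        "quarantine": 1.31,
        "financial_worries": 0.81,
        "own_reduced_work": 1.54,
        "partner_reduced_work": 0.98,
        "poor_mental_health": 2.07,
        "partner_poor_mental_health": 2.71,
        "childcare_hours": 0.97,
        "children_lt10": 5.31,
        "age": 0.99,
    }
    return GeneratorConfig(
        n_respondents=n,
        outcome_spec={
            "physical_conflict": OutcomeSpec(0.0309, women_ors),
            "corporal_punishment": OutcomeSpec(0.0658, child_ors, child_only=True),
        },
        disclosure_slope=0.0,
        scale_spec={
            "own_mental_health": ScaleSpec(4, 0.81),
            "partner_mental_health": ScaleSpec(4, 0.83),
            "financial_concerns": ScaleSpec(5, 0.84),
        },
        missingness={"partner_mental_health": 0.05, "childcare_hours": 0.0471},
        seed=seed,
    )


def refresh_quintile_flags(df) -> None:
    """Recompute top-quintile risk flags from (possibly imputed) scale scores."""
    for scale, flag in FLAG_COLUMNS.items():
        col = f"{scale}_score"
        if col in df.columns:
            df[flag] = top_quintile_flag(df[col].to_numpy(dtype=float))


def or_coverage_study(
    reps: int = 300,
    n: int = 3818,
    m: int = 10,
    seed: int = 0,
    track: dict[str, dict[str, float]] | None = None,
) -> dict:
    """Coverage of pooled 95% odds-ratio intervals over simulated surveys.

    Returns per-tracked-term coverage rates, mean odds-ratio estimates and
    the analytic sample sizes actually realized. ``track`` maps model name
    ("women"/"child") to {term: true OR}; defaults to the generating values
    of :func:`or_recovery_config`.
    """
    if track is None:
        track = {
            "women": {"quarantine": 2.38, "poor_mental_health": 3.41,
                      "financial_worries": 1.60, "childcare_hours": 1.07},
            "child": {"children_lt10": 5.31},
        }
    specs = {"women": women_predictor_spec(full=False), "child": child_predictor_spec(full=False)}
    outcomes = {"women": "direct_physical_conflict", "child": "direct_corporal_punishment"}

    covered = {mod: {t: 0 for t in terms} for mod, terms in track.items()}
    or_sums = {mod: {t: 0.0 for t in terms} for mod, terms in track.items()}
    n_analytic = {mod: [] for mod in track}

    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    for ss in child_seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        df = generate_dataset(or_recovery_config(n=n, seed=rep_seed))
        completed = chained_imputation(
            df, ["partner_mental_health_score"], m=m, seed=rep_seed
        )
        for comp in completed:
            refresh_quintile_flags(comp)
        for mod, terms in track.items():
            fit = fit_logistic_risk_model(completed, outcomes[mod], specs[mod])
            n_analytic[mod].append(fit.n_analytic)
            for term, truth in terms.items():
                res = fit.term(term)
                or_sums[mod][term] += res.odds_ratio
                if not res.separation and res.ci_low <= truth <= res.ci_high:
                    covered[mod][term] += 1

    return {
        "reps": reps,
        "coverage": {
            mod: {t: covered[mod][t] / reps for t in terms} for mod, terms in track.items()
        },
        "mean_or": {
            mod: {t: or_sums[mod][t] / reps for t in terms} for mod, terms in track.items()
        },
        "truth": track,
        "mean_n_analytic": {mod: float(np.mean(v)) for mod, v in n_analytic.items()},
    }
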