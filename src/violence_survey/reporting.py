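"""End-to-end orchestration and report rendering.

``run_pipeline`` takes either a generator configuration (simulate) or a
respondent-level table (analyze) and executes the full analysis in order:
descriptive shares, direct-elicitation prevalence with Wald intervals,
double-list estimates for the indirectly elicited outcomes, scale scoring
with internal consistency, the social-desirability disclosure gradient,
imputation-pooled logistic risk models, and predicted probabilities for
high- and low-risk covariate profiles. The result is a single
:class:`AnalysisReport` that serializes losslessly to JSON; every number in
the rendered tables is traceable to one of the upstream estimate objects.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .list_experiment import ListEstimate, double_list_estimate
from .prevalence import PrevalenceEstimate, descriptive_table, prevalence_table
from .recovery import refresh_quintile_flags
from .risk_models import (
    ProfilePrediction,
    RiskModelResult,
    RiskProfile,
    TermResult,
    chained_imputation,
    child_predictor_spec,
    fit_logistic_risk_model,
    predicted_probability,
    women_predictor_spec,
)
from .scales import GradientResult, cronbach_alpha, disclosure_gradient, pca_scale_score
from .synthetic_data import FLAG_COLUMNS, GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_pipeline", "render_report_text", "report_to_json", "report_from_json"]

DIRECT_OUTCOME_ORDER = (
    "verbal_conflict",
    "physical_conflict",
    "emotional_abuse_any",
    "threatened",
    "confined",
    "controlled",
    "corporal_punishment",
)

RISK_OUTCOME_ORDER = (
    "verbal_conflict",
    "physical_conflict",
    "threatened",
    "confined",
    "controlled",
    "corporal_punishment",
)

DEFAULT_HIGH_RISK = {
    "quarantine": 1,
    "financial_worries": 1,
    "own_reduced_work": 1,
    "partner_reduced_work": 1,
    "poor_mental_health": 1,
    "partner_poor_mental_health": 1,
    "children_lt10": 1,
}


@dataclass
class AnalysisReport:
    descriptives: list[PrevalenceEstimate] = field(default_factory=list)
    prevalence_direct: list[PrevalenceEstimate] = field(default_factory=list)
    prevalence_indirect: list[ListEstimate] = field(default_factory=list)
    scale_alphas: dict[str, float] = field(default_factory=dict)
    gradient: GradientResult | None = None
    risk_models: dict[str, RiskModelResult] = field(default_factory=dict)
    profile_predictions: list[ProfilePrediction] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# serialization (lossless round trip)

def report_to_json(report: AnalysisReport, indent: int = 2) -> str:
    payload = {
        "descriptives": [asdict(e) for e in report.descriptives],
        "prevalence_direct": [asdict(e) for e in report.prevalence_direct],
        "prevalence_indirect": [asdict(e) for e in report.prevalence_indirect],
        "scale_alphas": report.scale_alphas,
        "gradient": asdict(report.gradient) if report.gradient is not None else None,
        "risk_models": {k: asdict(v) for k, v in report.risk_models.items()},
        "profile_predictions": [asdict(p) for p in report.profile_predictions],
        "dropped": report.dropped,
        "provenance": report.provenance,
    }
    return json.dumps(payload, indent=indent, sort_keys=True)


def _tuplify(d: dict, keys) -> dict:
    for k in keys:
        if d.get(k) is not None:
            d[k] = tuple(d[k])
    return d


def report_from_json(text: str) -> AnalysisReport:
    p = json.loads(text)
    models = {}
    for k, v in p["risk_models"].items():
        v = _tuplify(dict(v), ["columns", "params", "design_means", "within_var", "between_var"])
        v["terms"] = tuple(TermResult(**t) for t in v["terms"])
        v["cov"] = tuple(tuple(row) for row in v["cov"])
        models[k] = RiskModelResult(**v)
    grad = None
    if p["gradient"] is not None:
        grad = GradientResult(**_tuplify(dict(p["gradient"]), ["rates", "counts"]))
    return AnalysisReport(
        descriptives=[PrevalenceEstimate(**e) for e in p["descriptives"]],
        prevalence_direct=[PrevalenceEstimate(**e) for e in p["prevalence_direct"]],
        prevalence_indirect=[
            ListEstimate(**_tuplify(dict(e), ["per_list_estimates"]))
            for e in p["prevalence_indirect"]
        ],
        scale_alphas=p["scale_alphas"],
        gradient=grad,
        risk_models=models,
        profile_predictions=[ProfilePrediction(**x) for x in p["profile_predictions"]],
        dropped={k: int(v) for k, v in p["dropped"].items()},
        provenance=p["provenance"],
    )


# ---------------------------------------------------------------------------
# pipeline

def _ensure_scores(df: pd.DataFrame) -> dict[str, float]:
    """Compute scale scores/flags from item batteries where absent; return alphas."""
    alphas: dict[str, float] = {}
    names = sorted({c.rsplit("_item", 1)[0] for c in df.columns if "_item" in c})
    for name in names:
        item_cols = [c for c in df.columns if c.startswith(f"{name}_item")]
        items = df[item_cols].to_numpy(dtype=float)
        try:
            alphas[name] = cronbach_alpha(items)
        except ValueError:
            continue
        if f"{name}_score" not in df.columns:
            ss = pca_scale_score(items, name=name)
            df[f"{name}_score"] = ss.scores
            if name in FLAG_COLUMNS:
                df[FLAG_COLUMNS[name]] = ss.top_quintile
    return alphas


def run_pipeline(
    config_or_data,
    *,
    m: int = 10,
    seed: int | None = None,
    full_model: bool = True,
    risk_outcomes=None,
    high_risk_profile: dict | None = None,
    outdir: str | Path | None = None,
) -> AnalysisReport:
    """Execute the full analysis and return an :class:`AnalysisReport`.

    Parameters
    ----------
    config_or_data
        A :class:`GeneratorConfig` (simulate first), a DataFrame, or a path
        to a respondent-level CSV.
    m
        Number of chained-imputation copies for the risk models.
    seed
        Seed for the imputation draws; defaults to the generator seed when
        simulating, else 0.
    full_model
        Full risk-factor specification (pandemic block + sociodemographics)
        vs the pandemic block + age only.
    risk_outcomes
        Outcomes to model; defaults to every directly elicited outcome found.
    high_risk_profile
        Covariate settings for the "Yes" profile; the "No" profile sets the
        same terms to zero. Defaults to all pandemic-related flags on.
    outdir
        If given, write ``report.json``, ``report.txt`` and CSV tables there.
    """
    if isinstance(config_or_data, GeneratorConfig):
        logger.info("simulating %d respondents (seed %d)", config_or_data.n_respondents,
                    config_or_data.seed)
        df = generate_dataset(config_or_data)
        if seed is None:
            seed = config_or_data.seed
    elif isinstance(config_or_data, (str, Path)):
        df = pd.read_csv(config_or_data)
    else:
        df = config_or_data.copy()
    if seed is None:
        seed = 0

    report = AnalysisReport()
    report.scale_alphas = _ensure_scores(df)

    # --- descriptives -----------------------------------------------------
    binary_candidates = [
        "cohabiting", "born_abroad", "children_lt10", "children_ge10", "employed",
        "partner_employed", "key_worker", "quarantine", "own_reduced_work",
        "partner_reduced_work",
    ]
    cat_candidates = ["education", "income", "region"]
    report.descriptives = descriptive_table(
        df,
        [c for c in binary_candidates if c in df.columns],
        [c for c in cat_candidates if c in df.columns],
    )

    # --- prevalence: direct then indirect ---------------------------------
    direct_cols = [c.removeprefix("direct_") for c in df.columns if c.startswith("direct_")]
    ordered = [o for o in DIRECT_OUTCOME_ORDER if o in direct_cols]
    ordered += [o for o in direct_cols if o not in ordered]
    report.prevalence_direct = prevalence_table(df, [f"direct_{o}" for o in ordered])

    list_outcomes = [c.removesuffix("_arm") for c in df.columns if c.endswith("_arm")]
    for o in list_outcomes:
        est = double_list_estimate(df, o)
        report.prevalence_indirect.append(est)
        if est.n_dropped:
            report.dropped[f"list:{o}"] = est.n_dropped

    # --- disclosure gradient ----------------------------------------------
    if "social_desirability_score" in df.columns and "direct_physical_conflict" in df.columns:
        report.gradient = disclosure_gradient(
            df, "physical_conflict", sd_scores=df["social_desirability_score"].to_numpy()
        )

    # --- risk models -------------------------------------------------------
    if risk_outcomes is None:
        risk_outcomes = [o for o in RISK_OUTCOME_ORDER if o in direct_cols]
    target = "partner_mental_health_score"
    if target in df.columns and df[target].isna().any():
        completed = chained_imputation(df, [target], m=m, seed=int(seed))
        for comp in completed:
            refresh_quintile_flags(comp)
        report.dropped["imputed:partner_mental_health"] = int(df[target].isna().sum())
    else:
        completed = [df]

    for outcome in risk_outcomes:
        spec = (
            child_predictor_spec(full=full_model)
            if outcome == "corporal_punishment"
            else women_predictor_spec(full=full_model)
        )
        try:
            fit = fit_logistic_risk_model(completed, f"direct_{outcome}", spec)
        except (KeyError, ValueError) as err:
            raise RuntimeError(f"risk model for {outcome!r} failed: {err}") from err
        report.risk_models[outcome] = fit
        report.dropped[f"model:{outcome}"] = int(df[f"direct_{outcome}"].notna().sum() - fit.n_analytic)

    # --- profile predictions ----------------------------------------------
    settings = DEFAULT_HIGH_RISK if high_risk_profile is None else high_risk_profile
    for outcome, fit in report.risk_models.items():
        usable = {k: v for k, v in settings.items() if k in fit.columns}
        if not usable:
            continue
        hi = RiskProfile.from_dict("high_risk", usable)
        lo = RiskProfile.from_dict("low_risk", {k: 0.0 for k in usable})
        report.profile_predictions.append(predicted_probability(fit, hi))
        report.profile_predictions.append(predicted_probability(fit, lo))

    # --- provenance --------------------------------------------------------
    from . import __version__

    cfg = df.attrs.get("config")
    if cfg is not None:
        blob = json.dumps(cfg, sort_keys=True, default=str)
    else:
        blob = json.dumps({"columns": sorted(df.columns), "n": len(df)})
    report.provenance = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "n_respondents": int(len(df)),
        "software_version": __version__,
    }

    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_to_json(report))
    (outdir / "report.txt").write_text(render_report_text(report))
    rows = [
        {"section": "direct", "outcome": e.name.removeprefix("direct_"),
         "count": e.count, "denominator": e.denominator, "estimate": e.format()}
        for e in report.prevalence_direct
    ]
    rows += [
        {"section": "indirect", "outcome": e.outcome, "count": "NA",
         "denominator": e.n_arm_a + e.n_arm_b, "estimate": e.format()}
        for e in report.prevalence_indirect
    ]
    pd.DataFrame(rows).to_csv(outdir / "prevalence.csv", index=False)
    for outcome, fit in report.risk_models.items():
        pd.DataFrame(
            [{"term": t.name, "odds_ratio_ci": t.format()} for t in fit.terms]
        ).to_csv(outdir / f"risk_{outcome}.csv", index=False)


def render_report_text(report: AnalysisReport) -> str:
    """Human-readable tables (two-decimal, half-up percents throughout)."""
    lines = []
    if report.descriptives:
        lines += ["Sample characteristics", "-" * 40]
        lines += [f"  {e.name:<38s} {e.count:>5d} ({e.format().split(' ')[0]})"
                  for e in report.descriptives]
        lines.append("")
    if report.prevalence_direct or report.prevalence_indirect:
        lines += ["Estimated prevalence (95% CI)", "-" * 40]
        if report.prevalence_direct:
            lines.append("Direct elicitation")
            for e in report.prevalence_direct:
                lines.append(f"  {e.name.removeprefix('direct_'):<30s} {e.count:>4d}  {e.format()}")
        if report.prevalence_indirect:
            lines.append("Indirect elicitation (double list experiment)")
            for e in report.prevalence_indirect:
                lines.append(f"  {e.outcome:<30s}   NA  {e.format()}")
        lines.append("")
    if report.scale_alphas:
        lines += ["Scale internal consistency (Cronbach's alpha)", "-" * 40]
        lines += [f"  {k:<30s} {v:.2f}" for k, v in report.scale_alphas.items()]
        lines.append("")
    if report.gradient is not None:
        g = report.gradient
        lines += [
            "Disclosure by social-desirability quintile "
            f"({g.outcome}; trend slope {g.slope:+.4f}, p={g.pvalue:.3g})",
            "-" * 40,
        ]
        lines += [f"  Q{i + 1}: {r:.2f}%  (n={c})" for i, (r, c) in enumerate(zip(g.rates, g.counts))]
        lines.append("")
    for outcome, fit in report.risk_models.items():
        lines += [f"Risk factors: {outcome} (n={fit.n_analytic}, m={fit.m_imputations})", "-" * 40]
        lines += [f"  {t.name:<34s} {t.format()}" for t in fit.terms]
        lines.append("")
    if report.profile_predictions:
        lines += ["Predicted probability by risk profile", "-" * 40]
        lines += [f"  {p.outcome:<24s} {p.profile:<10s} {p.format()}"
                  for p in report.profile_predictions]
        lines.append("")
    if report.provenance:
        lines += ["Provenance", "-" * 40]
        lines += [f"  {k}: {v}" for k, v in sorted(report.provenance.items())]
    return "\n".join(lines) + "\n"
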