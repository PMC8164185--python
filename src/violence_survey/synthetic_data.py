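"""Synthetic respondent-level survey data with known ground truth.

The generator emulates an online survey of partnered women during a lockdown:
sociodemographic covariates drawn from published sample marginals, Likert
item batteries calibrated to target internal consistencies, latent binary
violence outcomes from a logistic risk model with configurable odds ratios,
direct reports suppressed as a function of social-desirability sensitivity,
and double-list-experiment counts built from innocuous Bernoulli control
items plus the latent sensitive indicator. Missingness is applied last,
missing-completely-at-random.

Every stage draws from its own substream of one global seed, so datasets are
byte-identical across runs for the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .risk_models import predictor_column
from .scales import pca_scale_score

__all__ = [
    "ScaleSpec",
    "ListSpec",
    "OutcomeSpec",
    "GeneratorConfig",
    "default_config",
    "generate_dataset",
    "calibrate_scale_items",
    "invert_alpha",
    "implied_latent_prevalence",
    "write_dataset",
    "config_from_yaml",
    "list_recovery_config",
]

#: scale name -> derived top-quintile risk-flag column
FLAG_COLUMNS = {
    "own_mental_health": "poor_mental_health",
    "partner_mental_health": "partner_poor_mental_health",
    "financial_concerns": "financial_worries",
}

LIKERT_POINTS = 5


@dataclass(frozen=True)
class ScaleSpec:
    n_items: int
    target_alpha: float

    def validate(self, name: str = "") -> None:
        if self.n_items < 1:
            raise ValueError(f"scale {name}: n_items must be >= 1")
        if not 0 < self.target_alpha < 1:
            raise ValueError(f"scale {name}: target_alpha must be in (0, 1)")


@dataclass(frozen=True)
class ListSpec:
    n_control_items: int = 4
    control_item_probs: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

    def validate(self, name: str = "") -> None:
        if self.n_control_items < 1:
            raise ValueError(f"list {name}: need at least one control item")
        if len(self.control_item_probs) != self.n_control_items:
            raise ValueError(f"list {name}: one probability per control item required")
        if any(not 0 <= p <= 1 for p in self.control_item_probs):
            raise ValueError(f"list {name}: control item probabilities must be in [0, 1]")


@dataclass(frozen=True)
class OutcomeSpec:
    """Latent-outcome model: logit(p) = intercept + sum(log(OR) * x).

    ``baseline_prevalence`` is the *marginal* latent prevalence the intercept
    is calibrated to on the realized covariate draw. ``odds_ratios`` maps
    design-column keys (e.g. ``"quarantine"``, ``"education:lower_secondary"``)
    to strictly positive odds ratios.
    """

    baseline_prevalence: float
    odds_ratios: Mapping[str, float] = field(default_factory=dict)
    elicitation: str = "direct"  # "direct" | "list"
    child_only: bool = False

    def validate(self, name: str = "") -> None:
        if not 0 <= self.baseline_prevalence < 1:
            raise ValueError(f"outcome {name}: baseline_prevalence must be in [0, 1)")
        if self.elicitation not in ("direct", "list"):
            raise ValueError(f"outcome {name}: elicitation must be 'direct' or 'list'")
        if any(v <= 0 for v in self.odds_ratios.values()):
            raise ValueError(f"outcome {name}: odds ratios must be strictly positive")


def _default_child_rule(df: pd.DataFrame) -> np.ndarray:
    return ((df["children_lt10"] == 1) | (df["children_ge10"] == 1)).to_numpy()


def default_covariate_marginals() -> dict:
    """Published sample characteristics of the emulated survey (n = 3818)."""
    return {
        "quarantine": 0.1721,
        "cohabiting": 0.9099,
        "born_abroad": 0.1472,
        "children_lt10": 0.2546,
        "children_ge10": 0.1881,
        # 28.58% of households with reduced work/furlough for woman or partner,
        # split as two independent flags: 1 - (1 - p)^2 = 0.2858
        "own_reduced_work": 0.1552,
        "partner_reduced_work": 0.1552,
        "employed": 0.7444,
        "partner_employed": 0.7858,
        "key_worker": 0.2638,
        "education": {
            "middle_or_less": 0.3324,
            "lower_secondary": 0.2813,
            "higher_secondary": 0.3863,
        },
        "income": {
            "lt2000": 0.1980,
            "2000_4000": 0.4282,
            "gt4000": 0.2423,
            "no_answer": 0.1315,
        },
        "region": {"north": 0.1577, "east": 0.1977, "west": 0.3601, "south": 0.2844},
        "household_size": {1: 0.04, 2: 0.42, 3: 0.2977, 4: 0.155, 5: 0.06, 6: 0.0273},
        "age": ("uniform", 18.0, 65.0),
        "childcare_hours": ("uniform", 0.0, 12.0),  # zeroed without children
    }


def default_scale_specs() -> dict[str, ScaleSpec]:
    return {
        "own_mental_health": ScaleSpec(4, 0.81),
        "partner_mental_health": ScaleSpec(4, 0.83),
        "financial_concerns": ScaleSpec(5, 0.84),
        "social_desirability": ScaleSpec(6, 0.69),
    }


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """Direct outcomes with table-style odds ratios; list outcomes i.i.d.

    The marginal latent prevalences are set to the survey's point estimates;
    odds ratios for the direct outcomes follow the published risk-factor
    table column by column. Indirectly elicited (list) outcomes carry no
    covariate structure because they are excluded from regression modelling.
    """
    edu_lo, edu_hi = "education:lower_secondary", "education:higher_secondary"
    inc_mid, inc_hi, inc_na = "income:2000_4000", "income:gt4000", "income:no_answer"

    def ors(q, fw, orw, prw, mh, pmh, cc, c10, c10p, age, elo, ehi, im, ih, ina, emp, pemp, kw, hh, coh):
        d = {
            "quarantine": q,
            "financial_worries": fw,
            "own_reduced_work": orw,
            "partner_reduced_work": prw,
            "poor_mental_health": mh,
            "partner_poor_mental_health": pmh,
            "childcare_hours": cc,
            "children_lt10": c10,
            "age": age,
            edu_lo: elo,
            edu_hi: ehi,
            inc_mid: im,
            inc_hi: ih,
            inc_na: ina,
            "employed": emp,
            "partner_employed": pemp,
            "key_worker": kw,
            "household_size": hh,
            "cohabiting": coh,
        }
        if c10p is not None:
            d["children_ge10"] = c10p
        return d

    return {
        "verbal_conflict": OutcomeSpec(
            0.2533,
            ors(1.10, 0.95, 1.12, 1.18, 1.97, 2.17, 1.07, 1.44, 0.94, 0.97,
                1.18, 1.45, 0.96, 0.99, 0.86, 1.17, 0.77, 1.06, 0.98, 1.31),
        ),
        "physical_conflict": OutcomeSpec(
            0.0309,
            ors(2.38, 1.60, 2.07, 1.07, 3.41, 2.23, 1.01, 2.48, 1.36, 0.97,
                1.25, 0.97, 0.66, 0.21, 0.58, 0.77, 0.71, 2.35, 0.88, 1.39),
        ),
        "threatened": OutcomeSpec(
            0.0382,
            ors(1.43, 1.58, 1.17, 1.02, 2.97, 3.82, 1.06, 1.47, 1.22, 0.98,
                0.91, 0.69, 0.90, 0.61, 0.61, 0.80, 0.70, 1.74, 0.97, 1.04),
        ),
        "confined": OutcomeSpec(
            0.0223,
            ors(2.80, 1.29, 0.92, 1.25, 1.98, 4.12, 0.96, 2.23, 1.01, 0.99,
                1.28, 0.77, 0.49, 0.50, 0.15, 0.66, 1.32, 1.75, 1.04, 1.15),
        ),
        "controlled": OutcomeSpec(
            0.0458,
            ors(2.52, 1.22, 1.17, 0.84, 1.46, 2.82, 1.00, 1.84, 1.13, 0.98,
                1.01, 0.63, 0.71, 0.42, 0.35, 1.18, 0.58, 1.36, 1.15, 0.69),
        ),
        "corporal_punishment": OutcomeSpec(
            0.0658,
            ors(1.31, 0.81, 1.54, 0.98, 2.07, 2.71, 0.97, 5.31, None, 0.99,
                1.93, 2.08, 0.51, 0.37, 0.47, 0.89, 1.15, 1.12, 1.16, 0.95),
            child_only=True,
        ),
        "physical_violence": OutcomeSpec(0.0153, elicitation="list"),
        "sexual_violence": OutcomeSpec(0.0357, elicitation="list"),
        "child_physical_violence": OutcomeSpec(0.0197, elicitation="list", child_only=True),
    }


@dataclass
class GeneratorConfig:
    n_respondents: int = 3818
    covariate_marginals: dict = field(default_factory=default_covariate_marginals)
    outcome_spec: dict[str, OutcomeSpec] = field(default_factory=default_outcome_specs)
    disclosure_slope: float = -1.0
    scale_spec: dict[str, ScaleSpec] = field(default_factory=default_scale_specs)
    list_spec: dict[str, ListSpec] = field(default_factory=dict)
    child_subsample_rule: Callable[[pd.DataFrame], np.ndarray] = _default_child_rule
    missingness: dict[str, float] = field(
        default_factory=lambda: {"partner_mental_health": 0.05, "childcare_hours": 0.0471}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        for name, spec in self.covariate_marginals.items():
            if isinstance(spec, Mapping):
                probs = list(spec.values())
                if any(not 0 <= p <= 1 for p in probs):
                    raise ValueError(f"{name}: category probabilities must be in [0, 1]")
                # published shares carry rounding error; renormalized at draw time
                if abs(sum(probs) - 1.0) > 5e-3:
                    raise ValueError(f"{name}: category probabilities must sum to 1")
            elif isinstance(spec, tuple):
                kind, lo, hi = spec
                if kind != "uniform" or hi <= lo:
                    raise ValueError(f"{name}: continuous marginal must be ('uniform', lo, hi)")
            else:
                if not 0 <= float(spec) <= 1:
                    raise ValueError(f"{name}: probability must be in [0, 1]")
        for name, spec in self.outcome_spec.items():
            spec.validate(name)
        for name, spec in self.scale_spec.items():
            spec.validate(name)
        for name, spec in self.resolved_list_specs().items():
            spec.validate(name)
        for name, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name} must be in [0, 1]")

    def resolved_list_specs(self) -> dict[str, ListSpec]:
        return {
            name: self.list_spec.get(name, ListSpec())
            for name, spec in self.outcome_spec.items()
            if spec.elicitation == "list"
        }

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {
            f.name: enc(getattr(self, f.name))
            for f in dataclasses.fields(self)
            if f.name != "child_subsample_rule"
        }
        d["child_subsample_rule"] = "households_with_children"
        return d


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


def list_recovery_config(outcome: str, true_prevalence: float, n: int, seed: int) -> GeneratorConfig:
    """Minimal configuration for list-experiment recovery studies.

    One list outcome with an i.i.d. latent truth; no covariates, scales or
    missingness, so each replicate isolates the estimator's behaviour.
    """
    return GeneratorConfig(
        n_respondents=n,
        covariate_marginals={},
        outcome_spec={outcome: OutcomeSpec(true_prevalence, elicitation="list")},
        disclosure_slope=0.0,
        scale_spec={},
        missingness={},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scale-item calibration

def invert_alpha(target_alpha: float, k: int) -> float:
    """Inter-item correlation of k parallel items with Cronbach's alpha = target.

    Inverts alpha = k r / (1 + (k - 1) r).
    """
    if not 0 < target_alpha < 1:
        raise ValueError("target_alpha must be in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 items")
    return target_alpha / (k - (k - 1) * target_alpha)


def discretization_attenuation(n_points: int = LIKERT_POINTS) -> float:
    """Correlation attenuation factor from equal-probability Likert coarsening.

    For X standard normal cut into ``n_points`` equal-probability categories
    scored 0..n_points-1, corr(X, category) = sum_j phi(t_j) / sqrt((c^2-1)/12);
    the Pearson correlation between two discretized items is approximately
    lambda^2 times the latent correlation.
    """
    c = n_points
    t = norm.ppf(np.arange(1, c) / c)
    return float(norm.pdf(t).sum() / np.sqrt((c**2 - 1) / 12.0))


def calibrate_scale_items(
    scale_spec: ScaleSpec, n: int, rng: np.random.Generator | None = None, seed: int = 0
) -> np.ndarray:
    """Draw an (n, k) Likert item matrix whose expected Cronbach's alpha hits target.

    Items follow a one-factor model x_j = a F + sqrt(1 - a^2) e_j with the
    loading solved from the target alpha via the parallel-items identity,
    corrected for the attenuation introduced by 5-point discretization, then
    cut at equal-probability normal thresholds into integers 0..4.
    """
    scale_spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    k = scale_spec.n_items
    r = invert_alpha(scale_spec.target_alpha, k)
    lam = discretization_attenuation()
    r_latent = r / lam**2
    if r_latent >= 1.0:
        raise ValueError(
            f"target alpha {scale_spec.target_alpha} unreachable with {k} five-point items"
        )
    a = np.sqrt(r_latent)
    factor = rng.standard_normal(n)
    x = a * factor[:, None] + np.sqrt(1 - a**2) * rng.standard_normal((n, k))
    thresholds = norm.ppf(np.arange(1, LIKERT_POINTS) / LIKERT_POINTS)
    return np.searchsorted(thresholds, x, side="right").astype(np.int64)


# ---------------------------------------------------------------------------
# generation

def _draw_covariates(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    # iterate in sorted order so logically equal configs (e.g. round-tripped
    # through YAML, which sorts keys) consume the random stream identically
    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    for name in sorted(config.covariate_marginals):
        spec = config.covariate_marginals[name]
        if isinstance(spec, Mapping):
            levels = sorted(spec.keys(), key=str)
            probs = np.asarray([spec[k] for k in levels], dtype=float)
            probs = probs / probs.sum()
            df[name] = rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)
        elif isinstance(spec, tuple):
            _, lo, hi = spec
            df[name] = rng.uniform(lo, hi, size=n)
        else:
            df[name] = (rng.random(n) < float(spec)).astype(np.int64)
    if "childcare_hours" in df.columns and {"children_lt10", "children_ge10"} <= set(df.columns):
        has_children = (df["children_lt10"] == 1) | (df["children_ge10"] == 1)
        df.loc[~has_children, "childcare_hours"] = 0.0
    return df


def _add_scales(config: GeneratorConfig, df: pd.DataFrame, rng: np.random.Generator) -> None:
    for name in sorted(config.scale_spec):
        spec = config.scale_spec[name]
        items = calibrate_scale_items(spec, len(df), rng=rng)
        for j in range(spec.n_items):
            df[f"{name}_item{j + 1}"] = items[:, j]
        score = pca_scale_score(items, name=name)
        df[f"{name}_score"] = score.scores
        if name in FLAG_COLUMNS:
            df[FLAG_COLUMNS[name]] = score.top_quintile


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    if target == 0:
        return -np.inf
    if np.allclose(eta, 0.0):
        return float(logit(target))
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def _latent_eta(df: pd.DataFrame, spec: OutcomeSpec) -> np.ndarray:
    eta = np.zeros(len(df))
    for key, odds_ratio in spec.odds_ratios.items():
        x = predictor_column(df, key)
        if np.isnan(x).any():
            raise ValueError(f"predictor {key!r} has missing values at generation time")
        eta = eta + np.log(odds_ratio) * x
    return eta


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one respondent-level survey table.

    Returns a DataFrame with one row per respondent; ``df.attrs`` carries the
    resolved configuration and the calibrated latent intercepts. Column
    groups: covariates, ``{scale}_item*``/``{scale}_score`` plus derived risk
    flags, ``latent_true_{outcome}`` and ``direct_{outcome}`` for direct
    outcomes, and ``{outcome}_arm``/``{outcome}_list1``/``{outcome}_list2``
    for list outcomes. Child-only outcomes are defined only in households
    with children (NaN elsewhere).
    """
    config.validate()
    n = config.n_respondents
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cov, rng_scale, rng_out, rng_disc, rng_list, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    df = _draw_covariates(config, n, rng_cov)
    _add_scales(config, df, rng_scale)

    has_direct = any(s.elicitation == "direct" for s in config.outcome_spec.values())
    if has_direct and config.disclosure_slope != 0.0:
        if "social_desirability_score" not in df.columns:
            raise ValueError(
                "disclosure suppression requires a social_desirability scale"
            )
        sd = df["social_desirability_score"].to_numpy()
        z_sd = sd / sd.std(ddof=1)
        p_disclose = np.minimum(1.0, 2.0 * expit(config.disclosure_slope * z_sd))
    else:
        p_disclose = np.ones(n)

    try:
        child_mask = np.asarray(config.child_subsample_rule(df), dtype=bool)
    except KeyError:
        child_mask = np.zeros(n, dtype=bool)

    intercepts: dict[str, float] = {}
    list_specs = config.resolved_list_specs()
    for name in sorted(config.outcome_spec):
        spec = config.outcome_spec[name]
        mask = child_mask if spec.child_only else np.ones(n, dtype=bool)
        if spec.child_only and mask.sum() == 0:
            raise ValueError(f"outcome {name!r} is child-only but no household has children")
        eta = _latent_eta(df, spec)[mask]
        b0 = _calibrate_intercept(eta, spec.baseline_prevalence)
        p = expit(b0 + eta) if np.isfinite(b0) else np.zeros(mask.sum())
        latent = np.full(n, np.nan)
        latent[mask] = (rng_out.random(mask.sum()) < p).astype(float)
        df[f"latent_true_{name}"] = latent
        intercepts[name] = b0

        if spec.elicitation == "direct":
            disclosed = rng_disc.random(n) < p_disclose
            direct = np.full(n, np.nan)
            direct[mask] = latent[mask] * disclosed[mask]
            df[f"direct_{name}"] = direct
        else:
            lspec = list_specs[name]
            probs = np.asarray(lspec.control_item_probs, dtype=float)
            arm = np.where(rng_list.permutation(n) < n // 2, "A", "B")
            c1 = (rng_list.random((n, probs.size)) < probs).sum(axis=1).astype(float)
            c2 = (rng_list.random((n, probs.size)) < probs).sum(axis=1).astype(float)
            sens = np.nan_to_num(latent)
            l1 = c1 + np.where(arm == "A", sens, 0.0)
            l2 = c2 + np.where(arm == "B", sens, 0.0)
            arm_col = pd.Series(arm, index=df.index, dtype=object)
            arm_col[~mask] = np.nan
            l1[~mask] = np.nan
            l2[~mask] = np.nan
            df[f"{name}_arm"] = arm_col
            df[f"{name}_list1"] = l1
            df[f"{name}_list2"] = l2

    # derived "any emotional abuse" indicator where its components exist
    comp = [c for c in ("threatened", "confined", "controlled") if f"direct_{c}" in df.columns]
    if len(comp) == 3:
        df["direct_emotional_abuse_any"] = df[[f"direct_{c}" for c in comp]].max(axis=1)
        df["latent_true_emotional_abuse_any"] = df[[f"latent_true_{c}" for c in comp]].max(axis=1)

    _apply_missingness(config, df, rng_miss)

    df.attrs["config"] = config.to_dict()
    df.attrs["intercepts"] = intercepts
    return df


def _apply_missingness(config: GeneratorConfig, df: pd.DataFrame, rng: np.random.Generator) -> None:
    """MCAR blanking; scale names blank the whole battery plus derived columns."""
    for key in sorted(config.missingness):
        rate = config.missingness[key]
        if rate == 0:
            continue
        hit = rng.random(len(df)) < rate
        if key in config.scale_spec:
            cols = [f"{key}_item{j + 1}" for j in range(config.scale_spec[key].n_items)]
            cols.append(f"{key}_score")
            if key in FLAG_COLUMNS:
                cols.append(FLAG_COLUMNS[key])
        elif key in df.columns:
            cols = [key]
        else:
            raise KeyError(f"missingness target {key!r} not in dataset")
        for c in cols:
            df[c] = df[c].astype(float)
        df.loc[hit, cols] = np.nan


def implied_latent_prevalence(
    config: GeneratorConfig, outcome: str, intercept: float, n_mc: int = 200_000, seed: int = 12345
) -> float:
    """Numerically integrate the latent logistic model over the covariate law.

    Draws a fresh large covariate/scale sample, applies the calibrated
    intercept and averages the event probabilities — the prevalence the
    logistic model implies independent of any one generated dataset.
    """
    spec = config.outcome_spec[outcome]
    streams = np.random.SeedSequence(seed).spawn(2)
    df = _draw_covariates(config, n_mc, np.random.default_rng(streams[0]))
    _add_scales(config, df, np.random.default_rng(streams[1]))
    if spec.child_only:
        mask = np.asarray(config.child_subsample_rule(df), dtype=bool)
        df = df[mask].reset_index(drop=True)
    if not np.isfinite(intercept):
        return 0.0
    eta = _latent_eta(df, spec)
    return float(np.mean(expit(intercept + eta)))


# ---------------------------------------------------------------------------
# I/O

def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the respondent table as CSV plus a JSON sidecar with the
    resolved configuration, seed and calibrated intercepts."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    meta = {
        "config": df.attrs.get("config"),
        "intercepts": {
            k: (None if not np.isfinite(v) else v) for k, v in df.attrs.get("intercepts", {}).items()
        },
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    d.pop("child_subsample_rule", None)
    if "outcome_spec" in d:
        d["outcome_spec"] = {
            k: OutcomeSpec(**v) if not isinstance(v, OutcomeSpec) else v
            for k, v in d["outcome_spec"].items()
        }
    if "scale_spec" in d:
        d["scale_spec"] = {
            k: ScaleSpec(**v) if not isinstance(v, ScaleSpec) else v
            for k, v in d["scale_spec"].items()
        }
    if "list_spec" in d:
        out = {}
        for k, v in d["list_spec"].items():
            if not isinstance(v, ListSpec):
                v = dict(v)
                if "control_item_probs" in v:
                    v["control_item_probs"] = tuple(v["control_item_probs"])
                v = ListSpec(**v)
            out[k] = v
        d["list_spec"] = out
    if "covariate_marginals" in d:
        d["covariate_marginals"] = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d["covariate_marginals"].items()
        }
    return GeneratorConfig(**d)


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
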