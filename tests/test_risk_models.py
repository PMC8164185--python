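"""Logistic risk models, chained imputation, Rubin pooling, profile predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from violence_survey.risk_models import (
    PredictorSpec,
    RiskProfile,
    Term,
    chained_imputation,
    fit_logistic_risk_model,
    predicted_probability,
    rubin_pool,
)


def _binary_spec(*names):
    return PredictorSpec(terms=tuple(Term(n) for n in names))


def test_single_predictor_or_is_cross_product_ratio():
    df = pd.DataFrame(
        {
            "y": [1] * 20 + [0] * 80 + [1] * 10 + [0] * 90,
            "x": [1] * 100 + [0] * 100,
        }
    )
    fit = fit_logistic_risk_model(df, "y", _binary_spec("x"))
    assert fit.term("x").odds_ratio == pytest.approx((20 * 90) / (10 * 80), abs=1e-6)
    assert fit.n_analytic == 200


def test_rubin_rules_hand_computation():
    point, total, w, b = rubin_pool([0.5, 0.7], [0.1**2, 0.1**2])
    assert point == pytest.approx(0.6)
    assert w == pytest.approx(0.01)
    assert b == pytest.approx(0.02)
    assert total == pytest.approx(0.01 + 1.5 * 0.02)


def test_rubin_single_imputation_is_within_only():
    point, total, w, b = rubin_pool([0.4], [0.09])
    assert (point, total, b) == (0.4, 0.09, 0.0)


def test_pooling_identical_copies_equals_single_fit(rng):
    n = 600
    x = rng.random(n) < 0.3
    y = rng.random(n) < expit(-2 + 0.8 * x)
    df = pd.DataFrame({"y": y.astype(float), "x": x.astype(float)})
    single = fit_logistic_risk_model(df, "y", _binary_spec("x"))
    pooled = fit_logistic_risk_model([df.copy() for _ in range(3)], "y", _binary_spec("x"))
    assert pooled.term("x").odds_ratio == pytest.approx(single.term("x").odds_ratio, abs=1e-10)
    assert pooled.term("x").ci_low == pytest.approx(single.term("x").ci_low, abs=1e-8)
    assert pooled.between_var == pytest.approx(np.zeros(2), abs=1e-18)


def test_imputation_noop_without_missingness(rng):
    df = pd.DataFrame({"a": rng.random(50), "b": rng.random(50)})
    copies = chained_imputation(df, ["a"], m=3, seed=1)
    assert len(copies) == 3
    for c in copies:
        pd.testing.assert_frame_equal(c, df)


def test_imputation_seeded_determinism(rng):
    df = pd.DataFrame({"a": rng.random(200), "b": rng.random(200)})
    df.loc[df.index[:40], "a"] = np.nan
    c1 = chained_imputation(df, ["a"], m=4, seed=11)
    c2 = chained_imputation(df, ["a"], m=4, seed=11)
    c3 = chained_imputation(df, ["a"], m=4, seed=12)
    for a, b in zip(c1, c2):
        pd.testing.assert_frame_equal(a, b)
    assert not c1[0]["a"].equals(c3[0]["a"])


def test_imputation_requires_observed_values():
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError):
        chained_imputation(df, ["a"], m=2)
    with pytest.raises(KeyError):
        chained_imputation(df, ["zz"], m=2)


def test_imputation_recovers_full_data_odds_ratio(rng):
    """20% MCAR on a continuous predictor: the pooled OR should sit within
    10% of the odds ratio fitted on the pre-deletion dataset."""
    n = 5000
    score = rng.standard_normal(n)
    helper = 0.7 * score + rng.standard_normal(n) * 0.7  # auxiliary correlated covariate
    y = (rng.random(n) < expit(-2.0 + 0.6 * score)).astype(float)
    full = pd.DataFrame({"y": y, "score": score, "helper": helper})
    spec = PredictorSpec(terms=(Term("score", kind="continuous"),))
    truth = fit_logistic_risk_model(full, "y", spec).term("score").odds_ratio

    amputed = full.copy()
    amputed.loc[rng.random(n) < 0.2, "score"] = np.nan
    pooled = fit_logistic_risk_model(
        chained_imputation(amputed, ["score"], m=10, seed=5), "y", spec
    )
    assert pooled.term("score").odds_ratio == pytest.approx(truth, rel=0.10)


def test_null_model_coverage_near_nominal():
    """Outcome independent of the predictors: 95% CIs should cover OR = 1 at
    roughly the nominal rate."""
    rng = np.random.default_rng(77)
    spec = _binary_spec("x1", "x2", "x3")
    reps, covered = 500, np.zeros(3)
    for _ in range(reps):
        n = 400
        df = pd.DataFrame({f"x{i}": (rng.random(n) < 0.4).astype(float) for i in (1, 2, 3)})
        df["y"] = (rng.random(n) < 0.2).astype(float)
        fit = fit_logistic_risk_model(df, "y", spec)
        for i, name in enumerate(("x1", "x2", "x3")):
            t = fit.term(name)
            covered[i] += (not t.separation) and t.ci_low <= 1.0 <= t.ci_high
    for c in covered / reps:
        assert 0.92 <= c <= 0.985


def test_reference_recoding_inverts_category_or(rng):
    n = 2000
    edu = rng.choice(["low", "mid", "high"], n, p=[0.4, 0.35, 0.25])
    y = (rng.random(n) < expit(-1.5 + 0.5 * (edu == "high"))).astype(float)
    df = pd.DataFrame({"y": y, "edu": edu})
    ref_low = PredictorSpec(
        terms=(Term("edu", kind="categorical", reference="low", levels=("low", "mid", "high")),)
    )
    ref_high = PredictorSpec(
        terms=(Term("edu", kind="categorical", reference="high", levels=("low", "mid", "high")),)
    )
    a = fit_logistic_risk_model(df, "y", ref_low).term("edu:high").odds_ratio
    b = fit_logistic_risk_model(df, "y", ref_high).term("edu:low").odds_ratio
    assert a == pytest.approx(1.0 / b, rel=1e-6)


def test_reference_rows_rendered_as_unit_or():
    df = pd.DataFrame({"y": [0, 1] * 50, "x": [0.0, 1.0] * 50})
    spec = PredictorSpec(terms=(Term("x"),), reference_rows=("children_ge10",))
    fit = fit_logistic_risk_model(df, "y", spec)
    ref = fit.term("children_ge10")
    assert ref.reference and ref.odds_ratio == 1.0 and ref.ci_low is None
    assert ref.format() == "1.0 (–)"


def test_perfect_separation_flagged_not_crashed():
    df = pd.DataFrame({"y": [0] * 50 + [1] * 50, "x": [0.0] * 50 + [1.0] * 50})
    fit = fit_logistic_risk_model(df, "y", _binary_spec("x"))
    assert fit.term("x").separation
    assert fit.term("x").ci_low is None


def test_predicted_probability_intercept_only(rng):
    y = (rng.random(800) < 0.23).astype(float)
    df = pd.DataFrame({"y": y})
    fit = fit_logistic_risk_model(df, "y", PredictorSpec(terms=()))
    pred = predicted_probability(fit, RiskProfile("base", ()))
    assert pred.probability == pytest.approx(100 * y.mean(), abs=1e-6)


def test_predicted_probability_matches_plug_in_arithmetic(rng):
    n = 1500
    x1 = (rng.random(n) < 0.3).astype(float)
    x2 = rng.standard_normal(n)
    y = (rng.random(n) < expit(-1.0 + 0.9 * x1 + 0.4 * x2)).astype(float)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    spec = PredictorSpec(terms=(Term("x1"), Term("x2", kind="continuous")))
    fit = fit_logistic_risk_model(df, "y", spec)
    pred = predicted_probability(fit, RiskProfile.from_dict("hi", {"x1": 1.0}))
    beta = np.asarray(fit.params)
    x = np.array([1.0, 1.0, x2.mean()])
    assert pred.probability == pytest.approx(100 * expit(x @ beta), abs=1e-9)
    assert pred.ci_low < pred.probability < pred.ci_high


def test_high_risk_profile_exceeds_low_risk(rng):
    n = 3000
    x1 = (rng.random(n) < 0.25).astype(float)
    x2 = (rng.random(n) < 0.4).astype(float)
    y = (rng.random(n) < expit(-2.5 + 0.8 * x1 + 0.6 * x2)).astype(float)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    fit = fit_logistic_risk_model(df, "y", _binary_spec("x1", "x2"))
    hi = predicted_probability(fit, RiskProfile.from_dict("hi", {"x1": 1, "x2": 1}))
    lo = predicted_probability(fit, RiskProfile.from_dict("lo", {"x1": 0, "x2": 0}))
    assert hi.probability > lo.probability


def test_profile_with_unknown_term_errors(rng):
    df = pd.DataFrame({"y": (rng.random(100) < 0.5).astype(float), "x": rng.random(100)})
    fit = fit_logistic_risk_model(df, "y", PredictorSpec(terms=(Term("x", kind="continuous"),)))
    with pytest.raises(KeyError):
        predicted_probability(fit, RiskProfile.from_dict("bad", {"nope": 1}))


def test_statsmodels_agreement_on_multipredictor_fit(rng):
    """Dual route: pooled path with m=1 vs a direct statsmodels GLM fit."""
    n = 1200
    x = rng.random((n, 2))
    y = (rng.random(n) < expit(-1 + x @ np.array([0.7, -0.4]))).astype(float)
    df = pd.DataFrame({"y": y, "a": x[:, 0], "b": x[:, 1]})
    spec = PredictorSpec(terms=(Term("a", kind="continuous"), Term("b", kind="continuous")))
    fit = fit_logistic_risk_model(df, "y", spec)
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    assert np.allclose(fit.params, glm.params, atol=1e-6)
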