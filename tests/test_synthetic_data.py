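"""Generator contracts: marginals, determinism, disclosure, list-count bounds."""

import numpy as np
import pytest
import yaml

from violence_survey.synthetic_data import (
    GeneratorConfig,
    ListSpec,
    OutcomeSpec,
    ScaleSpec,
    config_from_dict,
    default_config,
    generate_dataset,
    implied_latent_prevalence,
    write_dataset,
)


def test_covariate_marginals_realized(default_dataset):
    df = default_dataset
    assert abs(df["quarantine"].mean() - 0.1721) < 0.015
    assert abs(df["cohabiting"].mean() - 0.9099) < 0.015
    assert abs((df["income"] == "2000_4000").mean() - 0.4282) < 0.02
    assert abs((df["household_size"] >= 4).mean() - 0.2423) < 0.02


def test_seeded_determinism_byte_identical(tmp_path):
    cfg = default_config(n_respondents=500, seed=99)
    p1 = write_dataset(generate_dataset(cfg), tmp_path / "a.csv")
    p2 = write_dataset(generate_dataset(default_config(n_respondents=500, seed=99)),
                       tmp_path / "b.csv")
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.json").exists()
    # a different seed must change the draw
    p3 = write_dataset(generate_dataset(default_config(n_respondents=500, seed=100)),
                       tmp_path / "c.csv")
    assert p1.read_bytes() != p3.read_bytes()


def test_zero_disclosure_slope_is_identity():
    """Without social-desirability suppression every latent case is reported."""
    for rep in range(500):
        cfg = GeneratorConfig(
            n_respondents=200,
            covariate_marginals={},
            outcome_spec={"physical_conflict": OutcomeSpec(0.05)},
            disclosure_slope=0.0,
            scale_spec={},
            missingness={},
            seed=rep,
        )
        df = generate_dataset(cfg)
        assert (df["direct_physical_conflict"] == df["latent_true_physical_conflict"]).all()


def test_list_count_bounds_hold_for_every_record(default_dataset):
    df = default_dataset
    for outcome in ("physical_violence", "sexual_violence", "child_physical_violence"):
        sub = df[[f"{outcome}_arm", f"{outcome}_list1", f"{outcome}_list2"]].dropna()
        arm = sub.iloc[:, 0].to_numpy()
        l1, l2 = sub.iloc[:, 1].to_numpy(), sub.iloc[:, 2].to_numpy()
        assert (l1 >= 0).all() and (l2 >= 0).all()
        # sensitive-bearing list may reach 5, the pure control list must not
        assert l1[arm == "A"].max() <= 5 and l2[arm == "A"].max() <= 4
        assert l2[arm == "B"].max() <= 5 and l1[arm == "B"].max() <= 4


def test_direct_report_never_fabricates(default_dataset):
    df = default_dataset
    for outcome in ("verbal_conflict", "physical_conflict", "corporal_punishment"):
        sub = df[[f"direct_{outcome}", f"latent_true_{outcome}"]].dropna()
        reported, latent = sub.iloc[:, 0], sub.iloc[:, 1]
        assert (latent[reported == 1] == 1).all()


def test_child_outcomes_confined_to_child_subsample(default_dataset):
    df = default_dataset
    has_children = (df["children_lt10"] == 1) | (df["children_ge10"] == 1)
    assert df.loc[~has_children, "latent_true_corporal_punishment"].isna().all()
    assert df.loc[has_children, "latent_true_corporal_punishment"].notna().all()
    assert df.loc[~has_children, "child_physical_violence_list1"].isna().all()


def test_disclosure_rate_nonincreasing_over_sd_quintiles():
    """Averaged over 200 replicates, the share of latent cases that get
    reported must not increase across social-desirability quintiles."""
    from violence_survey.scales import quintile_index

    disclosed = np.zeros(5)
    latent = np.zeros(5)
    for rep in range(200):
        cfg = GeneratorConfig(
            n_respondents=1000,
            covariate_marginals={},
            outcome_spec={"physical_conflict": OutcomeSpec(0.05)},
            disclosure_slope=-1.0,
            scale_spec={"social_desirability": ScaleSpec(6, 0.69)},
            missingness={},
            seed=50_000 + rep,
        )
        df = generate_dataset(cfg)
        q = quintile_index(df["social_desirability_score"].to_numpy())
        for j in range(1, 6):
            in_q = q == j
            latent[j - 1] += df.loc[in_q, "latent_true_physical_conflict"].sum()
            disclosed[j - 1] += df.loc[in_q, "direct_physical_conflict"].sum()
    rates = disclosed / latent
    assert all(rates[i + 1] <= rates[i] + 0.02 for i in range(4))
    assert rates[4] < rates[0] - 0.1  # the top quintile is clearly suppressed


def test_latent_prevalence_matches_numeric_integration():
    """MC mean latent prevalence vs integration of the logistic model over
    the covariate distribution, within 3 MC standard errors."""
    reps, prevs = 20, []
    intercept = None
    for rep in range(reps):
        df = generate_dataset(default_config(seed=300 + rep))
        prevs.append(df["latent_true_physical_conflict"].mean())
        if intercept is None:
            intercept = df.attrs["intercepts"]["physical_conflict"]
    implied = implied_latent_prevalence(
        default_config(seed=0), "physical_conflict", intercept, n_mc=100_000
    )
    mc_se = np.std(prevs, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(prevs) - implied) < 3 * mc_se


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_respondents=0),
        dict(covariate_marginals={"quarantine": 1.5}),
        dict(covariate_marginals={"education": {"a": 0.7, "b": 0.7}}),
        dict(outcome_spec={"x": OutcomeSpec(0.1, {"quarantine": -2.0})}),
        dict(missingness={"childcare_hours": 1.4}),
        dict(list_spec={"sexual_violence": ListSpec(n_control_items=0, control_item_probs=())}),
    ],
)
def test_invalid_configs_rejected(bad):
    cfg = default_config(**bad)
    with pytest.raises(ValueError):
        cfg.validate()


def test_config_yaml_roundtrip(tmp_path):
    cfg = default_config(n_respondents=400, seed=7)
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    cfg2 = config_from_dict(yaml.safe_load(path.read_text()))
    a = generate_dataset(cfg)
    b = generate_dataset(cfg2)
    assert a.to_csv(index=False) == b.to_csv(index=False)
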