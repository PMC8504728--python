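"""Log-log regression, nested-model comparison and relative weights."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pelvimetrics.errors import CollinearityError, DomainError, SchemaError
from pelvimetrics.inference import (
    RESPONSES,
    bodymass_groups,
    compare_interaction,
    fit_sex_model,
    log_transform,
    regression_report,
    relative_importance_table,
    relative_weights,
    significance_flags,
)
from pelvimetrics.synthetic import GeneratorConfig, simulate_cohort, true_effects


def _toy_cohort(n=20, rng=None, sex="female"):
    rng = rng or np.random.default_rng(0)
    gv = rng.uniform(3000, 6000, n)
    w = rng.uniform(50, 100, n)
    df = pd.DataFrame(
        dict(
            specimen_id=[f"s{i}" for i in range(n)],
            sex=sex,
            body_weight_kg=w,
            stature_m=1.7,
            gut_volume_cc=gv,
        )
    )
    for r in RESPONSES:
        df[r] = rng.uniform(0.8, 120.0, n)
    return df


def test_log_transform_values():
    df = _toy_cohort()
    df.loc[0, "gut_volume_cc"] = 1.0
    df.loc[1, "gut_volume_cc"] = np.e
    df.loc[2, "gut_volume_cc"] = np.e**2
    out = log_transform(df)
    assert out["gut_volume_cc"].iloc[0] == pytest.approx(0.0)
    assert out["gut_volume_cc"].iloc[1] == pytest.approx(1.0)
    assert out["gut_volume_cc"].iloc[2] == pytest.approx(2.0)
    assert out.attrs["scale"] == "log"


def test_log_of_ratio_equals_difference_of_logs():
    df = _toy_cohort()
    df["inlet_shape"] = df["IAP"] / df["IML"]
    out = log_transform(df)
    np.testing.assert_allclose(
        out["inlet_shape"], out["IAP"] - out["IML"], atol=1e-12
    )


def test_log_transform_names_offender():
    df = _toy_cohort()
    df.loc[3, "OML"] = -1.0
    with pytest.raises(DomainError, match="s3.*OML"):
        log_transform(df)


def test_noiseless_fit_recovers_coefficients_exactly():
    """log(resp) = 0.2 + 0.5 log GV + 0.3 log W interpolated to 1e-10."""
    df = _toy_cohort(n=30)
    df["IAP"] = np.exp(
        0.2 + 0.5 * np.log(df["gut_volume_cc"]) + 0.3 * np.log(df["body_weight_kg"])
    )
    rep = fit_sex_model(log_transform(df), "IAP", "female")
    assert rep.beta_gv == pytest.approx(0.5, abs=1e-10)
    assert rep.beta_weight == pytest.approx(0.3, abs=1e-10)
    assert rep.model_form == "additive"
    assert rep.beta_interaction is None


def test_male_model_includes_interaction():
    df = _toy_cohort(n=30, sex="male")
    rep = fit_sex_model(log_transform(df), "MML", "male")
    assert rep.model_form == "interaction"
    assert rep.beta_interaction is not None and np.isfinite(rep.p_interaction)


def test_unknown_response_rejected():
    df = log_transform(_toy_cohort())
    with pytest.raises(SchemaError):
        fit_sex_model(df, "femur_length", "female")


def test_null_response_has_negative_mean_adjusted_r2():
    """Independent response at n=44: adjusted R^2 is negative on average
    (negative values are legitimate report content)."""
    rng = np.random.default_rng(31)
    vals = []
    for _ in range(1000):
        df = _toy_cohort(n=44, rng=rng)
        vals.append(fit_sex_model(log_transform(df), "theta_b", "female").r2_adjusted)
    assert np.mean(vals) < 0.0


def test_interaction_coefficient_coverage_male():
    """95% CI for a generating interaction effect covers truth in most sims."""
    cfg = GeneratorConfig(seed=0, n_male=44, n_female=4)
    truth = true_effects(cfg, "male", "IML")[2]
    assert truth != 0
    rng = np.random.default_rng(4242)
    hits = 0
    n_sims = 250
    for _ in range(n_sims):
        coh = simulate_cohort(cfg, rng=rng)
        sub = log_transform(coh)
        sub = sub[sub["sex"] == "male"]
        X = sm.add_constant(
            pd.DataFrame(
                dict(
                    gv=sub["gut_volume_cc"],
                    w=sub["body_weight_kg"],
                    gw=sub["gut_volume_cc"] * sub["body_weight_kg"],
                )
            )
        )
        fit = sm.OLS(sub["IML"], X).fit()
        lo, hi = fit.conf_int().loc["gw"]
        hits += lo <= truth <= hi
    assert hits / n_sims >= 0.91  # Monte-Carlo slack around nominal 0.95


def test_compare_interaction_type_I_error():
    """Zero-interaction generator: the nested F-test rejects at ~0.05."""
    cfg = GeneratorConfig(seed=0, n_male=4, n_female=48)
    rng = np.random.default_rng(777)
    n_sims = 2000
    rejections = 0
    for _ in range(n_sims):
        coh = simulate_cohort(cfg, rng=rng)
        p = compare_interaction(log_transform(coh), "OAP", sex="female")
        rejections += p <= 0.05
    assert rejections / n_sims == pytest.approx(0.05, abs=0.02)


def test_compare_interaction_power():
    """A strong interaction (standardized effect ~0.8) is detected >90%."""
    rng = np.random.default_rng(55)
    rejections = 0
    n_sims = 500
    for _ in range(n_sims):
        n = 48
        gv = np.exp(rng.normal(8.3, 0.2, n))
        w = np.exp(rng.normal(4.2, 0.2, n))
        zg = (np.log(gv) - 8.3) / 0.2
        zw = (np.log(w) - 4.2) / 0.2
        resp = np.exp(0.8 * zg * zw * 0.05 + rng.normal(0, 0.05, n))
        df = pd.DataFrame(
            dict(
                specimen_id=[f"s{i}" for i in range(n)],
                sex="female",
                body_weight_kg=w,
                stature_m=1.6,
                gut_volume_cc=gv,
            )
        )
        for r in RESPONSES:
            df[r] = resp
        p = compare_interaction(log_transform(df), "IAP", sex="female")
        rejections += p <= 0.05
    assert rejections / n_sims > 0.9


def test_compare_interaction_degenerate_is_flagged():
    df = _toy_cohort(n=20)
    df["gut_volume_cc"] = 1.0  # log GV identically zero -> interaction adds no rank
    with pytest.raises((CollinearityError, SchemaError)):
        compare_interaction(log_transform(df), "IAP", sex="female")


def test_relative_weights_orthogonal_closed_form():
    """With in-sample orthogonalized predictors, eps_k = corr(x_k, y)^2."""
    rng = np.random.default_rng(8)
    n = 200
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal in sample
    x1, x2 = x1 - x1.mean(), x2 - x2.mean()
    x2 -= x1 * (x1 @ x2) / (x1 @ x1)
    y = 0.6 * x1 + 0.2 * x2 + rng.normal(size=n)
    pct, raw = relative_weights(np.column_stack([x1, x2]), y)
    r1 = np.corrcoef(x1, y)[0, 1] ** 2
    r2 = np.corrcoef(x2, y)[0, 1] ** 2
    assert raw[0] == pytest.approx(r1, abs=1e-10)
    assert raw[1] == pytest.approx(r2, abs=1e-10)
    assert raw.sum() == pytest.approx(r1 + r2, abs=1e-10)


def test_relative_weights_conserve_r2_and_are_label_invariant():
    rng = np.random.default_rng(9)
    for _ in range(25):
        n = int(rng.integers(30, 120))
        p = int(rng.integers(2, 7))
        X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        pct, raw = relative_weights(X, y)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert raw.sum() == pytest.approx(ols.rsquared, abs=1e-10)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
        perm = rng.permutation(p)
        pct_perm, _ = relative_weights(X[:, perm], y)
        np.testing.assert_allclose(pct_perm, pct[perm], atol=1e-9)


def test_relative_weights_one_relevant_orthogonal_predictor():
    rng = np.random.default_rng(10)
    n = 5000
    x1 = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = x1 + 0.1 * rng.normal(size=n)
    pct, _ = relative_weights(np.column_stack([x1, noise]), y)
    assert pct[0] > 97.0 and pct[1] < 3.0


def test_relative_weights_singular_predictors():
    rng = np.random.default_rng(12)
    x = rng.normal(size=100)
    with pytest.raises(CollinearityError):
        relative_weights(np.column_stack([x, 2 * x]), rng.normal(size=100))


@pytest.mark.parametrize(
    "p, flag", [(0.002, "**"), (0.01, "**"), (0.02, "*"), (0.05, "*"), (0.07, "")]
)
def test_significance_flags(p, flag):
    assert significance_flags(p) == flag


def test_significance_flags_domain():
    with pytest.raises(SchemaError):
        significance_flags(1.2)


def test_bodymass_groups_boundaries():
    df = pd.DataFrame(
        dict(
            specimen_id=["a", "b", "c", "d"],
            sex="female",
            body_weight_kg=[60.0, 70.0, 80.0, 90.0],
        )
    )
    labels = bodymass_groups(df, "female")
    w = df["body_weight_kg"].to_numpy()
    mean, sd = w.mean(), w.std(ddof=1)
    expected = np.where(w < mean - sd, "low", np.where(w > mean + sd, "high", "mid"))
    assert list(labels) == list(expected)


def test_bodymass_group_at_exact_boundary_is_mid():
    df = pd.DataFrame(
        dict(
            specimen_id=list("abc"),
            sex="male",
            body_weight_kg=[60.0, 70.0, 80.0],
        )
    )
    labels = bodymass_groups(df, "male")
    # mean 70, sd 10: 60 and 80 sit exactly on the boundaries -> mid
    assert list(labels) == ["mid", "mid", "mid"]


def test_report_structure_mirrors_summary_tables():
    cfg = GeneratorConfig(seed=2024, n_male=20, n_female=20)
    report = regression_report(log_transform(simulate_cohort(cfg)))
    assert len(report) == 22
    for sex in ("male", "female"):
        assert list(report[report.sex == sex]["response"]) == list(RESPONSES)
    np.testing.assert_allclose(report["rw_gv_pct"] + report["rw_weight_pct"], 100.0)
    assert (report["r2_raw"] >= np.maximum(report["r2"], 0.0) - 1e-12).all()
    imp = relative_importance_table(report)
    assert set(imp.columns) == {"sex", "response", "label", "rw_gv_pct", "rw_weight_pct"}
    assert (report.loc[report.model_p <= 0.01].shape[0]) == len(imp)
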