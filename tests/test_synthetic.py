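"""The generator's statistical structure and its round trips through the pipeline."""

import numpy as np
import pandas as pd
import pytest

from pelvimetrics.errors import ConfigError, InfeasibleGeometryError, ResolutionError
from pelvimetrics.inference import log_transform
from pelvimetrics.morphometry import compute_canal_dimensions, measure_all
from pelvimetrics.reliability import icc_absolute_agreement, ratings_from_long
from pelvimetrics.synthetic import (
    BASE_MEASURES,
    GeneratorConfig,
    landmarks_from_measurements,
    male_gv_intercept,
    simulate_cohort,
    simulate_landmark_sets,
    simulate_landmarks,
    simulate_mask_stack,
    true_effects,
)
from pelvimetrics.volumetry import gut_volume


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(seed=1, n_male=2)
    with pytest.raises(ConfigError):
        GeneratorConfig(seed=1, male_allometry_exponent=1.2)
    with pytest.raises(ConfigError):
        GeneratorConfig(seed=1, female_gv_mean=-5.0)
    with pytest.raises(ConfigError):
        GeneratorConfig(seed=1, canal_log_noise_sd=-0.1)


def test_null_generator_yields_identical_specimens():
    cfg = GeneratorConfig(
        seed=3,
        n_male=5,
        n_female=5,
        canal_log_noise_sd=0.0,
        canal_angle_log_noise_sd=0.0,
        female_effects={m: (0.0, 0.0) for m in BASE_MEASURES},
        male_effects={m: (0.0, 0.0, 0.0) for m in BASE_MEASURES},
    )
    coh = simulate_cohort(cfg)
    for m in BASE_MEASURES:
        np.testing.assert_allclose(coh[m], cfg.canal_template[m], rtol=1e-12)


def test_large_n_marginals_match_design():
    """Female weight-GV independence and the male log-log slope of 0.8."""
    cfg = GeneratorConfig(seed=17, n_male=10000, n_female=10000)
    coh = simulate_cohort(cfg)
    fem = coh[coh.sex == "female"]
    male = coh[coh.sex == "male"]
    corr = np.corrcoef(fem["body_weight_kg"], fem["gut_volume_cc"])[0, 1]
    assert abs(corr) < 0.03
    slope = np.polyfit(np.log(male["body_weight_kg"]), np.log(male["gut_volume_cc"]), 1)[0]
    assert slope == pytest.approx(0.8, abs=0.03)
    # Table-level moments
    assert fem["gut_volume_cc"].mean() == pytest.approx(4192.13, rel=0.02)
    assert fem["body_weight_kg"].mean() == pytest.approx(67.17, rel=0.02)
    assert male["body_weight_kg"].mean() == pytest.approx(80.43, rel=0.02)
    assert male["gut_volume_cc"].mean() == pytest.approx(5384.0, rel=0.02)


def test_female_gv_mean_unbiased_across_seeds():
    """Sample mean of female GV stays within 3 SEs of its target over seeds."""
    cfg = GeneratorConfig(seed=0, n_male=4, n_female=48)
    means = []
    rng = np.random.default_rng(606)
    for _ in range(500):
        coh = simulate_cohort(cfg, rng=rng)
        means.append(coh.loc[coh.sex == "female", "gut_volume_cc"].mean())
    se = 912.44 / np.sqrt(48) / np.sqrt(500)
    assert np.mean(means) == pytest.approx(4192.13, abs=3 * se)


def test_determinism_same_seed_same_output():
    cfg = GeneratorConfig(seed=99, n_male=8, n_female=8)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    la = measure_all(simulate_landmark_sets(a, cfg))
    lb = measure_all(simulate_landmark_sets(b, cfg))
    pd.testing.assert_frame_equal(la, lb)


def test_landmark_round_trip_noiseless(small_config):
    cfg = small_config.with_(
        landmark_noise_sd=0.0, fuzzy_landmark_noise_sd=0.0, observer_bias_sd=0.0
    )
    coh = simulate_cohort(cfg)
    rng = np.random.default_rng(1)
    for _, row in coh.head(5).iterrows():
        lms = simulate_landmarks(row, cfg, rng)
        assert len(lms) == cfg.n_observers * cfg.n_fuzzy_replicates
        meas = compute_canal_dimensions(lms[0])
        for m in BASE_MEASURES:
            assert getattr(meas, m) == pytest.approx(row[m], abs=1e-6)


def test_template_scaling_doubles_lengths_not_angles():
    base = {m: v for m, v in GeneratorConfig(seed=1).canal_template.items()}
    doubled = dict(base)
    for m in ("IAP", "IML", "MAP", "MML", "OAP", "OML"):
        doubled[m] = 2 * base[m]
    m1 = compute_canal_dimensions(landmarks_from_measurements(base))
    m2 = compute_canal_dimensions(landmarks_from_measurements(doubled))
    for m in ("IAP", "IML", "MAP", "MML", "OAP", "OML"):
        assert getattr(m2, m) == pytest.approx(2 * getattr(m1, m), rel=1e-9)
    assert m2.theta_a == pytest.approx(m1.theta_a, abs=1e-9)
    assert m2.theta_b == pytest.approx(m1.theta_b, abs=1e-9)


def test_infeasible_angles_raise():
    meas = dict(GeneratorConfig(seed=1).canal_template)
    meas["theta_a"], meas["theta_b"] = 120.0, 70.0  # sums past 180
    with pytest.raises(InfeasibleGeometryError):
        landmarks_from_measurements(meas)


def test_fuzzy_noise_drives_oml_icc_down():
    """Observer jitter 1 mm everywhere, 5 mm on the tuberosities: OML's ICC
    ends up below the sharp measures' in the bulk of runs."""
    wins, iap_high = 0, 0
    n_runs = 60
    for s in range(n_runs):
        cfg = GeneratorConfig(
            seed=5000 + s, n_male=4, n_female=42,
            landmark_noise_sd=1.0, fuzzy_landmark_noise_sd=5.0, observer_bias_sd=0.3,
        )
        coh = simulate_cohort(cfg)
        meas = measure_all(simulate_landmark_sets(coh, cfg))
        per_obs = (
            meas.drop(columns="replicate_id")
            .groupby(["specimen_id", "observer_id"], as_index=False)
            .mean()
        )
        long = per_obs.melt(
            id_vars=["specimen_id", "observer_id"],
            var_name="measurement_name",
            value_name="value",
        )
        iccs = {
            m: icc_absolute_agreement(ratings_from_long(long, m)).estimate
            for m in ("IAP", "IML", "MML", "OML")
        }
        iap_high += iccs["IAP"] > 0.9
        wins += iccs["OML"] < min(iccs["IAP"], iccs["IML"], iccs["MML"])
    assert iap_high / n_runs > 0.8
    assert wins / n_runs > 0.8


def test_pipeline_parameter_recovery_coverage():
    """Generate -> place landmarks -> measure -> regress: the 95% CI for the
    female theta_a gut-volume effect covers truth in >= 93% of 500 runs."""
    import statsmodels.api as sm

    cfg = GeneratorConfig(seed=0, n_male=4, n_female=48, n_observers=1)
    truth = true_effects(cfg, "female", "theta_a")[0]
    rng = np.random.default_rng(1234)
    hits = 0
    n_runs = 500
    for _ in range(n_runs):
        coh = simulate_cohort(cfg, rng=rng)
        fem = coh[coh.sex == "female"].reset_index(drop=True)
        lms = []
        for _, row in fem.iterrows():
            lms.extend(simulate_landmarks(row, cfg, rng))
        meas = (
            measure_all(lms)
            .drop(columns=["observer_id", "replicate_id"])
            .groupby("specimen_id", as_index=False)
            .mean()
        )
        merged = fem[["specimen_id", "sex", "body_weight_kg", "stature_m",
                      "gut_volume_cc"]].merge(meas, on="specimen_id")
        logd = log_transform(merged)
        X = sm.add_constant(
            np.column_stack([logd["gut_volume_cc"], logd["body_weight_kg"]])
        )
        fit = sm.OLS(logd["theta_a"].to_numpy(), X).fit()
        lo, hi = fit.conf_int()[1]
        hits += lo <= truth <= hi
    assert hits / n_runs >= 0.93


def test_mask_stack_hits_target():
    for target in (0.5, 120.0, 4192.0):
        stack = simulate_mask_stack(target)
        vol = gut_volume(stack)
        assert vol.volume_cc == pytest.approx(target, rel=0.01)
        assert stack.slice_thickness == 5.0


def test_mask_stack_tiny_target_exact():
    stack = simulate_mask_stack(0.5)  # 100 voxels at (1,1,5)
    assert gut_volume(stack).volume_cc == pytest.approx(0.5, abs=1e-12)


def test_mask_additivity_of_disjoint_blobs():
    import numpy as np

    a = simulate_mask_stack(12.0)
    b = simulate_mask_stack(30.0)
    ny = max(a.slices.shape[1], b.slices.shape[1])
    nx = max(a.slices.shape[2], b.slices.shape[2])

    def pad(s):
        out = np.zeros((s.shape[0], ny, nx), bool)
        out[:, : s.shape[1], : s.shape[2]] = s
        return out

    from pelvimetrics.volumetry import MaskStack

    combo = MaskStack(
        np.concatenate([pad(a.slices), pad(b.slices)]), (1.0, 1.0), 5.0
    )
    assert gut_volume(combo).volume_cc == pytest.approx(
        gut_volume(a).volume_cc + gut_volume(b).volume_cc
    )


def test_mask_below_resolution_raises():
    with pytest.raises(ResolutionError):
        simulate_mask_stack(0.001)


def test_male_intercept_hits_mean_gv():
    cfg = GeneratorConfig(seed=5)
    a = male_gv_intercept(cfg)
    assert np.isfinite(a)
    # direct Monte-Carlo check of the calibration
    rng = np.random.default_rng(42)
    w = rng.normal(cfg.male_weight_mean, cfg.male_weight_sd, 400000)
    w = w[w > 0]
    gv = np.exp(a + 0.8 * np.log(w) + rng.normal(0, cfg.male_gv_log_sd, w.size))
    assert gv.mean() == pytest.approx(5384.0, rel=0.01)
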