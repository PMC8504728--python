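"""Synthetic cohorts, landmark configurations and mask stacks with known truth.

The generator emulates the statistical structure the analysis assumes, with
every effect size configurable, so each pipeline stage has a
parameter-recovery test surface:

* per-sex body weight and stature are truncated-normal with the study
  cohort's moments (males 80.43 +- 19.27 kg, females 67.17 +- 13.15 kg);
* female gut volume is truncated-normal (4192.13 +- 912.44 cc) and
  *independent* of weight; male gut volume scales with weight with negative
  allometry, log GV = a + b log W + noise with exponent b = 0.8 by default
  and the intercept solved so the mean GV matches the male 5384 cc target;
* each of the eight base canal measures (six linear dimensions, two angles)
  is generated in log space from a template value plus linear effects of
  log GV and log weight (plus their product in males) and residual noise;
  the three shape indices follow as AP/ML ratios;
* landmarks are placed on a constructive template that reproduces a row's
  measurements exactly before noise, then perturbed by per-observer
  systematic bias and random jitter — with inflated jitter on the ischial
  tuberosities, the "fuzzy" landmarks behind the outlet ML diameter, which
  are re-placed per replicate;
* gut masks are nearest-to-center voxel blobs hitting a volume target to
  within half a voxel at the study's 5 mm slab geometry.

Template landmark coordinates are constructive defaults yielding realistic
pelvic magnitudes; they carry no claim of matching any real sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InfeasibleGeometryError, ResolutionError
from .morphometry import LandmarkSet
from .volumetry import MaskStack

#: The eight directly generated measures; shape indices are derived ratios.
BASE_MEASURES: tuple[str, ...] = (
    "IAP", "IML", "MAP", "MML", "OAP", "OML", "theta_a", "theta_b",
)

_SHAPE_PARENTS = {
    "inlet_shape": ("IAP", "IML"),
    "midplane_shape": ("MAP", "MML"),
    "outlet_shape": ("OAP", "OML"),
}

#: Fuzzy landmarks: re-placed per replicate with inflated jitter.
FUZZY_LANDMARKS: tuple[str, ...] = ("ischial_tuberosity_L", "ischial_tuberosity_R")


def _default_template() -> dict[str, float]:
    # Realistic adult canal magnitudes (mm / degrees).
    return {
        "IAP": 110.0, "IML": 125.0, "MAP": 115.0, "MML": 100.0,
        "OAP": 95.0, "OML": 115.0, "theta_a": 72.0, "theta_b": 54.0,
    }


def _default_female_effects() -> dict[str, tuple[float, float]]:
    # (beta_gv, beta_weight) on each log base measure; additive model.
    return {
        "IAP": (0.029, 0.032),
        "IML": (0.074, 0.030),
        "MAP": (0.038, 0.13),
        "MML": (0.059, -0.075),
        "OAP": (0.071, 0.16),
        "OML": (0.024, -0.11),
        "theta_a": (-0.11, -0.099),
        "theta_b": (0.26, 0.16),
    }


def _default_male_effects() -> dict[str, tuple[float, float, float]]:
    # (beta_gv, beta_weight, beta_interaction); modest ML widening of the
    # inlet and midplane with gut size, stronger in heavier individuals.
    return {
        "IAP": (0.01, 0.02, 0.000),
        "IML": (0.04, 0.04, 0.015),
        "MAP": (0.01, 0.02, 0.000),
        "MML": (0.03, 0.03, 0.015),
        "OAP": (0.01, 0.02, 0.000),
        "OML": (0.01, 0.02, 0.000),
        "theta_a": (0.01, 0.01, 0.000),
        "theta_b": (0.01, 0.02, 0.000),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with the cohort's defaults."""

    seed: int
    n_male: int = 44
    n_female: int = 48
    # Body weight (kg) and stature (m), per sex
    male_weight_mean: float = 80.43
    male_weight_sd: float = 19.27
    female_weight_mean: float = 67.17
    female_weight_sd: float = 13.15
    male_stature_mean: float = 1.77
    male_stature_sd: float = 0.07
    female_stature_mean: float = 1.64
    female_stature_sd: float = 0.07
    # Gut volume (cc)
    female_gv_mean: float = 4192.13
    female_gv_sd: float = 912.44
    male_gv_mean: float = 5384.0
    male_allometry_exponent: float = 0.8
    male_gv_log_sd: float = 0.148
    # Canal generation.  Residual log-SDs: larger scatter on the linear
    # dimensions keeps the emulated models' explanatory power in the modest
    # range real canal~GV+weight fits show; the smaller angle scatter keeps
    # the spine triangle feasible under multiplicative noise.
    canal_template: dict[str, float] = field(default_factory=_default_template)
    canal_log_noise_sd: float = 0.12
    canal_angle_log_noise_sd: float = 0.05
    female_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_female_effects
    )
    male_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_male_effects
    )
    # Landmark observation model
    landmark_noise_sd: float = 1.0
    fuzzy_landmark_noise_sd: float = 5.0
    observer_bias_sd: float = 0.5
    n_observers: int = 2
    n_fuzzy_replicates: int = 2
    # Mask geometry
    mask_pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        if self.n_male < 4 or self.n_female < 4:
            raise ConfigError("need at least 4 specimens per sex")
        sds = (
            self.male_weight_sd, self.female_weight_sd, self.female_gv_sd,
            self.male_gv_log_sd, self.canal_log_noise_sd,
            self.canal_angle_log_noise_sd,
            self.landmark_noise_sd, self.fuzzy_landmark_noise_sd,
            self.observer_bias_sd,
        )
        if any(s < 0 for s in sds):
            raise ConfigError("standard deviations must be >= 0")
        if not 0 < self.male_allometry_exponent < 1:
            raise ConfigError(
                "male allometric exponent must lie in (0, 1) (negative allometry)"
            )
        for mean, what in (
            (self.male_weight_mean, "male weight"),
            (self.female_weight_mean, "female weight"),
            (self.female_gv_mean, "female gut volume"),
            (self.male_gv_mean, "male gut volume"),
        ):
            if mean <= 0:
                raise ConfigError(f"{what} mean must be positive (truncation at 0)")
        missing = [m for m in BASE_MEASURES if m not in self.canal_template]
        if missing:
            raise ConfigError(f"canal template missing measures {missing}")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Truncated-normal helpers (truncation at zero)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _trunc_moment(mean: float, sd: float, func: str, power: float = 1.0) -> float:
    """E[f(X)] for X ~ Normal(mean, sd) truncated to X > 0."""
    if sd == 0:
        x = mean
        return math.log(x) if func == "log" else x**power
    dist = stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)
    if func == "log":
        return float(dist.expect(np.log))
    return float(dist.expect(lambda x: x**power))


def _sample_positive_normal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def male_gv_intercept(cfg: GeneratorConfig) -> float:
    """Intercept a of log GV = a + b log W + eps matching the male mean GV."""
    b = cfg.male_allometry_exponent
    e_wb = _trunc_moment(cfg.male_weight_mean, cfg.male_weight_sd, "pow", b)
    return math.log(cfg.male_gv_mean) - math.log(e_wb) - cfg.male_gv_log_sd**2 / 2.0


def true_effects(cfg: GeneratorConfig, sex: str, response: str) -> tuple[float, ...]:
    """Generating (beta_gv, beta_weight[, beta_interaction]) for any response.

    Shape indices inherit the difference of their AP and ML parents' effects,
    since log(AP/ML) = log AP - log ML.
    """
    table = cfg.male_effects if sex == "male" else cfg.female_effects
    if response in table:
        return tuple(table[response])
    ap, ml = _SHAPE_PARENTS[response]
    return tuple(a - m for a, m in zip(table[ap], table[ml]))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _centering(cfg: GeneratorConfig, sex: str) -> tuple[float, float]:
    """Analytic (E[log GV], E[log W]) used to anchor templates at the mean."""
    if sex == "female":
        c_w = _trunc_moment(cfg.female_weight_mean, cfg.female_weight_sd, "log")
        c_g = _trunc_moment(cfg.female_gv_mean, cfg.female_gv_sd, "log")
    else:
        c_w = _trunc_moment(cfg.male_weight_mean, cfg.male_weight_sd, "log")
        c_g = male_gv_intercept(cfg) + cfg.male_allometry_exponent * c_w
    return c_g, c_w


def simulate_cohort(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One synthetic cohort table: ids, sex, weight, stature, GV, canal measures."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frames = []
    for sex, n in (("male", cfg.n_male), ("female", cfg.n_female)):
        if sex == "male":
            w = _sample_positive_normal(rng, cfg.male_weight_mean, cfg.male_weight_sd, n)
            stat = _sample_positive_normal(rng, cfg.male_stature_mean, cfg.male_stature_sd, n)
            a = male_gv_intercept(cfg)
            log_gv = (
                a
                + cfg.male_allometry_exponent * np.log(w)
                + rng.normal(0.0, cfg.male_gv_log_sd, size=n)
            )
            gv = np.exp(log_gv)
        else:
            w = _sample_positive_normal(rng, cfg.female_weight_mean, cfg.female_weight_sd, n)
            stat = _sample_positive_normal(rng, cfg.female_stature_mean, cfg.female_stature_sd, n)
            gv = _sample_positive_normal(rng, cfg.female_gv_mean, cfg.female_gv_sd, n)
            log_gv = np.log(gv)
        log_w = np.log(w)
        c_g, c_w = _centering(cfg, sex)
        data = dict(
            specimen_id=[f"{sex[0].upper()}{i + 1:03d}" for i in range(n)],
            sex=sex,
            body_weight_kg=w,
            stature_m=stat,
            gut_volume_cc=gv,
        )
        for meas in BASE_MEASURES:
            eff = true_effects(cfg, sex, meas)
            bg, bw = eff[0], eff[1]
            bi = eff[2] if len(eff) == 3 else 0.0
            lin = (
                math.log(cfg.canal_template[meas])
                + bg * (log_gv - c_g)
                + bw * (log_w - c_w)
                + bi * (log_gv * log_w - c_g * c_w)
            )
            noise_sd = (
                cfg.canal_angle_log_noise_sd
                if meas in ("theta_a", "theta_b")
                else cfg.canal_log_noise_sd
            )
            data[meas] = np.exp(lin + rng.normal(0.0, noise_sd, size=n))
        df = pd.DataFrame(data)
        for shape, (ap, ml) in _SHAPE_PARENTS.items():
            df[shape] = df[ap] / df[ml]
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    cols = [
        "specimen_id", "sex", "body_weight_kg", "stature_m", "gut_volume_cc",
        "IAP", "IML", "inlet_shape", "MAP", "MML", "midplane_shape",
        "OAP", "OML", "outlet_shape", "theta_a", "theta_b",
    ]
    return cohort[cols]


# ---------------------------------------------------------------------------
# Landmark simulation
# ---------------------------------------------------------------------------


def landmarks_from_measurements(
    measures: dict[str, float],
    specimen_id: str = "template",
    observer_id: str = "generator",
    replicate_id: int = 1,
) -> LandmarkSet:
    """Constructive landmark placement reproducing eight base measures exactly.

    The spine triangle is solved from MML, theta_a and theta_b (law of
    sines); the remaining landmarks are placed along fixed unit directions at
    the prescribed interlandmark distances.  Frame: x mediolateral (left
    negative), y anteroposterior (anterior positive), z axial.
    """
    mml, iml, oml = measures["MML"], measures["IML"], measures["OML"]
    iap, map_, oap = measures["IAP"], measures["MAP"], measures["OAP"]
    ta, tb = measures["theta_a"], measures["theta_b"]
    if not (0 < ta < 180 and 0 < tb < 180) or ta + tb >= 180:
        raise InfeasibleGeometryError(
            f"no spine triangle with theta_a={ta:.2f}, theta_b={tb:.2f} deg "
            "(angles must be positive and sum to < 180)"
        )
    ta_r, tb_r = math.radians(ta), math.radians(tb)
    gamma = math.pi - ta_r - tb_r
    sl = mml * math.sin(gamma) / math.sin(ta_r)  # left spine -> S5 apex

    spine_l = np.array([-mml / 2.0, 0.0, 0.0])
    spine_r = np.array([+mml / 2.0, 0.0, 0.0])
    apex = spine_l + sl * np.array([math.cos(tb_r), -math.sin(tb_r), 0.0])
    symph_inf = apex + np.array([0.0, oap, 0.0])
    alpha = 0.4  # fixed posterior-superior tilt of the sacral segment
    s4s5 = symph_inf + map_ * np.array([0.0, -math.cos(alpha), math.sin(alpha)])
    prom = s4s5 + 40.0 * np.array([0.0, -0.2, math.sqrt(1 - 0.04)])
    beta = math.radians(15.0)
    symph_sup = prom + iap * np.array([0.0, math.cos(beta), -math.sin(beta)])
    coords = {
        "ischial_spine_L": spine_l,
        "ischial_spine_R": spine_r,
        "ischial_tuberosity_L": np.array([-oml / 2.0, 10.0, -35.0]),
        "ischial_tuberosity_R": np.array([+oml / 2.0, 10.0, -35.0]),
        "sacral_promontory": prom,
        "between_S4_S5": s4s5,
        "apex_S5": apex,
        "dorsal_sup_pubic_symphysis": symph_sup,
        "dorsal_inf_pubic_symphysis": symph_inf,
        "max_iliopectineal_L": np.array([-iml / 2.0, 30.0, 40.0]),
        "max_iliopectineal_R": np.array([+iml / 2.0, 30.0, 40.0]),
    }
    return LandmarkSet(
        specimen_id=specimen_id,
        observer_id=observer_id,
        replicate_id=replicate_id,
        coords=coords,
    )


def observer_biases(cfg: GeneratorConfig) -> dict[str, dict[str, np.ndarray]]:
    """Per-observer systematic placement offsets, fixed across specimens."""
    from .morphometry import LANDMARK_NAMES

    biases: dict[str, dict[str, np.ndarray]] = {}
    for i in range(cfg.n_observers):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 777, i]))
        biases[f"obs{i + 1}"] = {
            name: rng.normal(0.0, cfg.observer_bias_sd, size=3)
            for name in LANDMARK_NAMES
        }
    return biases


def simulate_landmarks(
    row,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    biases: dict[str, dict[str, np.ndarray]] | None = None,
) -> list[LandmarkSet]:
    """Observed landmark sets (observers x replicates) for one cohort row.

    Non-fuzzy landmarks get one observer-level jitter shared across
    replicates (replicates re-place only the fuzzy tuberosities), so the
    replicate-averaging contract of the reliability stage holds by
    construction.
    """
    measures = {m: float(row[m]) for m in BASE_MEASURES}
    clean = landmarks_from_measurements(measures, specimen_id=str(row["specimen_id"]))
    if biases is None:
        biases = observer_biases(cfg)
    out = []
    for obs_id, bias in biases.items():
        obs_jitter = {
            name: rng.normal(0.0, cfg.landmark_noise_sd, size=3)
            for name in clean.coords
            if name not in FUZZY_LANDMARKS
        }
        for rep in range(1, cfg.n_fuzzy_replicates + 1):
            coords = {}
            for name, xyz in clean.coords.items():
                if name in FUZZY_LANDMARKS:
                    noise = rng.normal(0.0, cfg.fuzzy_landmark_noise_sd, size=3)
                else:
                    noise = obs_jitter[name]
                coords[name] = xyz + bias[name] + noise
            out.append(
                LandmarkSet(
                    specimen_id=clean.specimen_id,
                    observer_id=obs_id,
                    replicate_id=rep,
                    coords=coords,
                )
            )
    return out


def simulate_landmark_sets(
    cohort: pd.DataFrame, cfg: GeneratorConfig
) -> list[LandmarkSet]:
    """Landmark sets for every cohort row, deterministically from cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31337]))
    biases = observer_biases(cfg)
    out: list[LandmarkSet] = []
    for _, row in cohort.iterrows():
        out.extend(simulate_landmarks(row, cfg, rng, biases=biases))
    return out


# ---------------------------------------------------------------------------
# Mask simulation
# ---------------------------------------------------------------------------


def simulate_mask_stack(
    gv_target: float,
    cfg: GeneratorConfig | None = None,
    specimen_id: str = "synthetic",
    pixel_spacing: tuple[float, float] | None = None,
    slice_thickness: float | None = None,
) -> MaskStack:
    """A voxel blob whose slice-summation volume hits ``gv_target`` (cc).

    The blob is the set of voxels nearest the grid center, filled until the
    target voxel count is reached, so the volume is exact to within half a
    voxel (far inside 1% at the default 1 mm / 5 mm geometry for any
    realistic gut volume).
    """
    if pixel_spacing is None:
        pixel_spacing = cfg.mask_pixel_spacing if cfg else (1.0, 1.0)
    if slice_thickness is None:
        slice_thickness = cfg.slice_thickness if cfg else 5.0
    rs, cs = pixel_spacing
    voxel_mm3 = rs * cs * slice_thickness
    target_mm3 = gv_target * 1000.0
    needed = int(round(target_mm3 / voxel_mm3))
    if gv_target <= 0 or needed < 1:
        raise ResolutionError(
            f"target {gv_target} cc is below one voxel ({voxel_mm3 / 1000.0} cc)"
        )
    r_ideal = (3.0 * target_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    nz = max(1, int(math.ceil(2.0 * r_ideal / slice_thickness)) + 1)
    ny = int(math.ceil(2.0 * r_ideal / rs)) + 3
    nx = int(math.ceil(2.0 * r_ideal / cs)) + 3
    z = ((np.arange(nz) + 0.5) - nz / 2.0) * slice_thickness
    y = ((np.arange(ny) + 0.5) - ny / 2.0) * rs
    x = ((np.arange(nx) + 0.5) - nx / 2.0) * cs
    d2 = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    ).ravel()
    if needed > d2.size:  # extreme anisotropy can starve the snug grid
        side = int(math.ceil(math.sqrt(needed))) + 2
        return _cuboid_stack(needed, side, pixel_spacing, slice_thickness, specimen_id)
    order = np.argsort(d2, kind="stable")[:needed]
    mask = np.zeros(nz * ny * nx, dtype=bool)
    mask[order] = True
    return MaskStack(
        slices=mask.reshape(nz, ny, nx),
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
        specimen_id=specimen_id,
    )


def _cuboid_stack(needed, side, pixel_spacing, slice_thickness, specimen_id):
    nz = max(1, int(math.ceil(needed / (side * side))))
    mask = np.zeros(nz * side * side, dtype=bool)
    mask[:needed] = True
    return MaskStack(
        slices=mask.reshape(nz, side, side),
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
        specimen_id=specimen_id,
    )
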