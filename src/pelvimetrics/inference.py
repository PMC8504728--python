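"""Sex-specific allometric regression of canal measures on gut volume and weight.

All variables are natural-log transformed, then each of the 11 canal
responses (six linear dimensions, three shape indices, two angles) is
regressed on log gut volume (GV) and log body weight by ordinary least
squares — with a GV x weight interaction in males, where GV scales with
negative allometry on weight, and additively in females, where GV and weight
are independent:

    males:    log(canal) ~ log(GV) * log(weight)
    females:  log(canal) ~ log(GV) + log(weight)

The headline "R^2" of a model is the *adjusted* R^2 (which can legitimately
be negative for uninformative models); the raw R^2 is reported alongside it
and is the quantity the relative-weights decomposition partitions.

Relative weights (Johnson's epsilon) decompose the raw R^2 into
non-negative per-predictor shares: with predictor correlation matrix
R_xx = V diag(lambda) V', its symmetric square root Lambda = V diag(sqrt
lambda) V', and beta = Lambda^{-1} r_xy, the raw weights are
eps = (Lambda o Lambda)(beta o beta) (elementwise squares), which sum exactly
to R^2.  They are computed for the two main predictors (GV, weight) in both
sexes, so every model yields two percentages summing to 100.

Significance is flagged at a conservative alpha of 0.01 ("**"), with
0.01 < p <= 0.05 noted ("*"); no multiple-testing correction is applied
across the 11 responses (the tightened alpha plays that role), and the
number of tests run is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import (
    CollinearityError,
    DataAlignmentError,
    DomainError,
    SchemaError,
)
from .morphometry import FIELD_ORDER

log = logging.getLogger(__name__)

#: The 11 canal responses, in report (Table) order.
RESPONSES: tuple[str, ...] = FIELD_ORDER

#: Human-readable report labels for the responses.
RESPONSE_LABELS: dict[str, str] = {
    "IAP": "IAP",
    "IML": "IML",
    "inlet_shape": "Inlet (AP/ML)",
    "MAP": "MAP",
    "MML": "MML",
    "midplane_shape": "Midplane (AP/ML)",
    "OAP": "OAP",
    "OML": "OML",
    "outlet_shape": "Outlet (AP/ML)",
    "theta_a": "Ischial Spine Projection",
    "theta_b": "S5 Position",
}

_PREDICTORS = ("gut_volume_cc", "body_weight_kg")
_LOGGED_FIELDS = _PREDICTORS + RESPONSES


@dataclass(frozen=True)
class FitReport:
    """One response x sex regression summary (Table-style row)."""

    response_name: str
    sex: str
    model_form: str  # "interaction" | "additive"
    n: int
    beta_gv: float
    p_gv: float
    beta_weight: float
    p_weight: float
    r2_adjusted: float
    r2_raw: float
    model_p: float
    rw_gv_pct: float
    rw_weight_pct: float
    beta_interaction: float | None = None
    p_interaction: float | None = None

    def __post_init__(self) -> None:
        if abs(self.rw_gv_pct + self.rw_weight_pct - 100.0) > 1e-6:
            raise SchemaError(
                f"relative weights must sum to 100, got "
                f"{self.rw_gv_pct} + {self.rw_weight_pct}"
            )
        if self.r2_raw < max(0.0, self.r2_adjusted) - 1e-12:
            raise SchemaError(
                f"raw R^2 ({self.r2_raw}) below adjusted ({self.r2_adjusted})"
            )

    @property
    def flag_gv(self) -> str:
        return significance_flags(self.p_gv)

    @property
    def flag_weight(self) -> str:
        return significance_flags(self.p_weight)

    @property
    def flag_model(self) -> str:
        return significance_flags(self.model_p)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    required = ["specimen_id", "sex", "body_weight_kg", "gut_volume_cc", *RESPONSES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s) {missing}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise SchemaError(f"duplicated specimen_id(s) {dupes}")
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise SchemaError(f"sex must be 'male' or 'female', got {sorted(bad_sex)}")
    return df


def log_transform(cohort: pd.DataFrame) -> pd.DataFrame:
    """Natural log of GV, body weight and all canal measures.

    Shape ratios and angles are transformed like every other value; the
    returned frame records the original units in ``attrs``.
    """
    df = validate_cohort(cohort).copy()
    for field in _LOGGED_FIELDS:
        vals = df[field].to_numpy(dtype=float)
        bad = ~(np.isfinite(vals) & (vals > 0))
        if bad.any():
            culprit = df.loc[bad, "specimen_id"].iloc[0]
            raise DomainError(
                f"specimen {culprit!r}: field {field!r} is not strictly "
                "positive, cannot log-transform"
            )
        df[field] = np.log(vals)
    df.attrs["scale"] = "log"
    df.attrs["log_base"] = "e"
    return df


def _sex_frame(cohort_log: pd.DataFrame, sex: str) -> pd.DataFrame:
    if cohort_log.attrs.get("scale") != "log":
        raise SchemaError("cohort must be log-transformed first (log_transform)")
    sub = cohort_log[cohort_log["sex"] == sex].copy()
    if sub.empty:
        raise SchemaError(f"no specimens with sex {sex!r}")
    sub = sub.rename(columns={"gut_volume_cc": "gv", "body_weight_kg": "weight"})
    return sub


def fit_sex_model(cohort_log: pd.DataFrame, response_name: str, sex: str) -> FitReport:
    """OLS fit of one canal response for one sex, with relative weights."""
    if response_name not in RESPONSES:
        raise SchemaError(f"unknown response {response_name!r}")
    sub = _sex_frame(cohort_log, sex)
    interaction = sex == "male"
    formula = (
        f"{response_name} ~ gv * weight" if interaction
        else f"{response_name} ~ gv + weight"
    )
    n_params = 4 if interaction else 3
    if len(sub) < n_params + 1:
        raise SchemaError(
            f"{sex}: need at least {n_params + 1} specimens to fit "
            f"{formula!r}, have {len(sub)}"
        )
    model = smf.ols(formula, data=sub)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise CollinearityError(f"{sex}/{response_name}: rank-deficient design")
    fit = model.fit()

    rw_pct, _ = relative_weights(
        sub[["gv", "weight"]].to_numpy(), sub[response_name].to_numpy()
    )
    return FitReport(
        response_name=response_name,
        sex=sex,
        model_form="interaction" if interaction else "additive",
        n=int(fit.nobs),
        beta_gv=float(fit.params["gv"]),
        p_gv=float(fit.pvalues["gv"]),
        beta_weight=float(fit.params["weight"]),
        p_weight=float(fit.pvalues["weight"]),
        beta_interaction=float(fit.params["gv:weight"]) if interaction else None,
        p_interaction=float(fit.pvalues["gv:weight"]) if interaction else None,
        r2_adjusted=float(fit.rsquared_adj),
        r2_raw=float(fit.rsquared),
        model_p=float(fit.f_pvalue),
        rw_gv_pct=float(rw_pct[0]),
        rw_weight_pct=float(rw_pct[1]),
    )


def compare_interaction(
    cohort_log: pd.DataFrame, response_name: str, sex: str = "female"
) -> float:
    """F-test p-value: does a GV x weight interaction improve the additive model?"""
    sub = _sex_frame(cohort_log, sex)
    additive = smf.ols(f"{response_name} ~ gv + weight", data=sub)
    full = smf.ols(f"{response_name} ~ gv * weight", data=sub)
    if additive.exog.shape[0] != full.exog.shape[0]:
        raise DataAlignmentError("nested models were built on different rows")
    if np.linalg.matrix_rank(full.exog) <= np.linalg.matrix_rank(additive.exog):
        raise CollinearityError(
            f"{sex}/{response_name}: interaction term adds no rank "
            "(degenerate comparison)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(additive.fit(), full.fit())
    return float(table["Pr(>F)"].iloc[1])


def relative_weights(
    predictors: np.ndarray, response: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Johnson relative weights: per-predictor share of the raw R^2.

    Returns ``(percentages, raw_weights)``; the raw weights sum to the OLS
    raw R^2 of the response on the predictors, the percentages to 100.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise SchemaError("relative weights need >= 2 predictors")
    if X.shape[0] != y.shape[0]:
        raise DataAlignmentError("predictor and response row counts differ")

    rxx = np.corrcoef(X, rowvar=False)
    rxy = np.array(
        [np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])]
    )
    lam, vec = np.linalg.eigh(rxx)
    if lam.min() <= 1e-10:
        raise CollinearityError(
            f"predictor correlation matrix is singular (min eigenvalue {lam.min():.3g})"
        )
    sqrt_rxx = vec @ np.diag(np.sqrt(lam)) @ vec.T
    beta = np.linalg.solve(sqrt_rxx, rxy)
    raw = (sqrt_rxx**2) @ (beta**2)
    total = raw.sum()
    if total <= 0:
        raise CollinearityError("response has zero linear association with predictors")
    return 100.0 * raw / total, raw


def significance_flags(p: float) -> str:
    """Report flag: '**' for p<=0.01, '*' for p<=0.05, '' otherwise."""
    if not (np.isfinite(p) and 0.0 <= p <= 1.0):
        raise SchemaError(f"p-value must be in [0, 1], got {p}")
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def bodymass_groups(cohort: pd.DataFrame, sex: str) -> pd.Series:
    """Label specimens low / mid / high by body weight vs the per-sex mean +- 1 SD.

    Strictly below mean - SD is "low", strictly above mean + SD is "high";
    everything else (boundaries included) is "mid".
    """
    sub = cohort[cohort["sex"] == sex]
    if len(sub) < 2:
        raise SchemaError(f"need >= 2 specimens of sex {sex!r} to form groups")
    w = sub["body_weight_kg"].to_numpy(dtype=float)
    mean, sd = w.mean(), w.std(ddof=1)
    if sd == 0:
        warnings.warn(
            f"{sex}: zero body-weight variance, all specimens in one group",
            stacklevel=2,
        )
    labels = np.where(w < mean - sd, "low", np.where(w > mean + sd, "high", "mid"))
    return pd.Series(labels, index=sub.index, name="bodymass_group")


# ---------------------------------------------------------------------------
# Report assembly (regression summary + relative-importance tables)
# ---------------------------------------------------------------------------


def regression_report(cohort_log: pd.DataFrame) -> pd.DataFrame:
    """Full per-sex regression summary: 11 response rows per sex.

    Columns mirror the conventional summary layout — per-predictor betas and
    p-values with flags, adjusted R^2 as the headline R^2, raw R^2, overall
    model p — plus the two relative-weight percentages.
    """
    rows = []
    n_tests = 0
    for sex in ("male", "female"):
        for resp in RESPONSES:
            rep = fit_sex_model(cohort_log, resp, sex)
            n_tests += 1
            rows.append(
                dict(
                    sex=sex,
                    response=resp,
                    label=RESPONSE_LABELS[resp],
                    n=rep.n,
                    beta_gv=rep.beta_gv,
                    p_gv=rep.p_gv,
                    flag_gv=rep.flag_gv,
                    beta_weight=rep.beta_weight,
                    p_weight=rep.p_weight,
                    flag_weight=rep.flag_weight,
                    beta_interaction=rep.beta_interaction,
                    p_interaction=rep.p_interaction,
                    r2=rep.r2_adjusted,
                    r2_raw=rep.r2_raw,
                    model_p=rep.model_p,
                    flag_model=rep.flag_model,
                    rw_gv_pct=rep.rw_gv_pct,
                    rw_weight_pct=rep.rw_weight_pct,
                )
            )
    log.info("regression_report: %d response-level model tests, no multiple-"
             "testing correction (alpha tightened to 0.01 instead)", n_tests)
    return pd.DataFrame(rows)


def relative_importance_table(report: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Relative-weight percentages for models significant at ``alpha``."""
    sig = report[report["model_p"] <= alpha]
    return sig[["sex", "response", "label", "rw_gv_pct", "rw_weight_pct"]].reset_index(
        drop=True
    )


def plot_response_by_group(
    cohort: pd.DataFrame, response: str, sex: str, ax=None
):
    """Scatter of a log response vs log GV with per-bodymass-group fit lines."""
    import matplotlib.pyplot as plt

    sub = cohort[cohort["sex"] == sex]
    groups = bodymass_groups(cohort, sex)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    shades = {"low": 0.25, "mid": 0.55, "high": 0.9}
    base = "tab:green" if sex == "male" else "tab:orange"
    for name in ("low", "mid", "high"):
        pts = sub[groups == name]
        if pts.empty:
            continue
        x = pts["gut_volume_cc"].to_numpy()
        y = pts[response].to_numpy()
        ax.scatter(x, y, color=base, alpha=shades[name], label=f"{name} body mass")
        if len(pts) >= 2 and np.ptp(x) > 0:
            coef = np.polyfit(x, y, 1)
            xx = np.linspace(x.min(), x.max(), 20)
            ax.plot(xx, np.polyval(coef, xx), color=base, alpha=shades[name])
    ax.set_xlabel("log GV")
    ax.set_ylabel(f"log {RESPONSE_LABELS[response]}")
    ax.set_title(f"{sex}: {RESPONSE_LABELS[response]}")
    ax.legend(fontsize=7)
    return ax
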