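"""Observer agreement: two-way absolute-agreement ICC and fuzzy-landmark rules.

Inter- and intra-observer error on a measurement is quantified with the
single-rater, absolute-agreement intraclass correlation from the two-way
ANOVA decomposition (ICC(A,1) in the McGraw & Wong taxonomy, ICC(2,1) in
Shrout & Fleiss's).  "Absolute agreement" penalizes systematic rater offsets
as well as inconsistency, which is the right notion when raters re-measure
the same physical quantity on the same specimen.

With n subjects and k raters, mean squares MSR (rows/subjects), MSC
(columns/raters) and MSE (residual):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

The 95% confidence interval uses the F-based method with Satterthwaite
degrees of freedom (McGraw & Wong 1996).  The study design this mirrors
described its interval as a "95% tolerance level"; it is implemented here as
the conventional 95% confidence interval of that framework.

Landmarks without a sharply defined anatomical point ("fuzzy" landmarks —
here the ischial tuberosities that define the outlet ML diameter) are
measured in replicate and the replicate average is carried into analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InconsistentReplicatesError, SchemaError, UndefinedICCError
from .morphometry import CanalMeasurements

log = logging.getLogger(__name__)

#: Canal fields measured from fuzzy landmarks, averaged across replicates.
DEFAULT_FUZZY_FIELDS = frozenset({"OML"})

#: Shape indices recomputed after fuzzy averaging, with their (AP, ML) parents.
_SHAPE_PARENTS = {
    "inlet_shape": ("IAP", "IML"),
    "midplane_shape": ("MAP", "MML"),
    "outlet_shape": ("OAP", "OML"),
}


@dataclass(frozen=True)
class RatingsMatrix:
    """n_subjects x k_raters matrix of one measurement."""

    values: np.ndarray
    measurement_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise SchemaError(f"ratings must be 2D (subjects x raters), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise SchemaError("ratings matrix contains missing/non-finite cells")
        n, k = v.shape
        if n < 2 or k < 2:
            raise SchemaError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    measurement_name: str = ""
    model: str = "two-way, absolute agreement, single rater"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise SchemaError(
                f"ICC interval [{self.ci_low}, {self.ci_high}] does not "
                f"bracket the estimate {self.estimate}"
            )


def ratings_from_long(
    df: pd.DataFrame,
    measurement_name: str,
    subject_col: str = "specimen_id",
    rater_col: str = "observer_id",
    value_col: str = "value",
) -> RatingsMatrix:
    """Pivot a long table into a ratings matrix, dropping incomplete subjects."""
    sub = df[df["measurement_name"] == measurement_name] if "measurement_name" in df else df
    wide = sub.pivot_table(
        index=subject_col, columns=rater_col, values=value_col, aggfunc="mean"
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        log.warning(
            "%s: dropped %d of %d subjects with missing ratings",
            measurement_name, n_dropped, len(wide),
        )
    return RatingsMatrix(values=complete.to_numpy(), measurement_name=measurement_name)


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((values - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(r: RatingsMatrix, confidence: float = 0.95) -> ICCResult:
    """Single-rater absolute-agreement ICC with its F-based confidence interval."""
    n, k = r.n, r.k
    msr, msc, mse = _two_way_mean_squares(r.values)

    scale = float(np.var(r.values)) + float(np.mean(r.values)) ** 2
    if msr <= 1e-12 * max(scale, 1e-12):
        raise UndefinedICCError(
            f"{r.measurement_name or 'ratings'}: zero between-subject variance, "
            "the ICC is undefined"
        )

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        # Perfect agreement: no error or rater variance at any level.
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a) or np.isinf(b):
            nu = (n - 1) * (k - 1)
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            nu = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, nu)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, nu, n - 1)
        lo = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        hi = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(
        estimate=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        k=k,
        measurement_name=r.measurement_name,
    )


def classify_agreement(estimate: float) -> str:
    """Conventional ICC interpretation bands (thresholds closed on the left)."""
    if not np.isfinite(estimate):
        raise SchemaError(f"ICC estimate must be finite, got {estimate}")
    if estimate >= 0.90:
        return "excellent"
    if estimate >= 0.75:
        return "good"
    if estimate >= 0.50:
        return "moderate"
    return "poor"


def average_fuzzy_replicates(
    measurements: list[CanalMeasurements],
    fuzzy_fields: frozenset[str] | set[str] = DEFAULT_FUZZY_FIELDS,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> CanalMeasurements:
    """Collapse replicate measurements by averaging the fuzzy-flagged fields.

    Replicates are repeat placements of the fuzzy landmarks only, so every
    non-fuzzy field must agree across replicates (within tolerance); shape
    indices whose ML parent is fuzzy are recomputed from the averaged value
    (the average *measurement* is what enters analysis, not an average of
    ratios).
    """
    if not measurements:
        raise SchemaError("no replicates to average")
    if len(measurements) == 1:
        return measurements[0]

    fuzzy = set(fuzzy_fields)
    derived = {
        shape for shape, (ap, ml) in _SHAPE_PARENTS.items()
        if ap in fuzzy or ml in fuzzy
    }
    first = measurements[0]
    fixed_fields = [
        f
        for f in (CanalMeasurements.LINEAR_FIELDS + CanalMeasurements.ANGLE_FIELDS
                  + CanalMeasurements.SHAPE_FIELDS)
        if f not in fuzzy and f not in derived
    ]
    for i, m in enumerate(measurements[1:], start=2):
        for f in fixed_fields:
            a, b = getattr(first, f), getattr(m, f)
            if not np.isclose(a, b, rtol=rtol, atol=atol):
                raise InconsistentReplicatesError(
                    f"replicate {i} disagrees with replicate 1 on non-fuzzy "
                    f"field {f!r}: {b} vs {a}"
                )

    updates = {
        f: float(np.mean([getattr(m, f) for m in measurements])) for f in fuzzy
    }
    merged = replace(first, **updates)
    shape_updates = {
        shape: getattr(merged, ap) / getattr(merged, ml)
        for shape, (ap, ml) in _SHAPE_PARENTS.items()
        if shape in derived
    }
    if shape_updates:
        merged = replace(merged, **shape_updates)
    return merged


def icc_report(
    df: pd.DataFrame,
    measurement_names: list[str] | None = None,
) -> pd.DataFrame:
    """ICC table for a long measurements frame, one row per measurement."""
    if measurement_names is None:
        measurement_names = sorted(df["measurement_name"].unique())
    rows = []
    for name in measurement_names:
        res = icc_absolute_agreement(ratings_from_long(df, name))
        rows.append(
            dict(
                measurement_name=name,
                icc=res.estimate,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                n=res.n,
                k=res.k,
                agreement=classify_agreement(res.estimate),
                model=res.model,
            )
        )
    return pd.DataFrame(rows)
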