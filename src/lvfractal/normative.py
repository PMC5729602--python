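"""Normative reference ranges and classification.

Reference ranges are 95% prediction intervals from a univariable linear
regression of the metric on age, stratified by sex.  At age x the limits
are

    (a + b*x) +/- t_{0.975, n-2} * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)

where s is the residual standard deviation.  Each limit additionally
carries an *indeterminate region*: its own 95% confidence interval,
estimated by a case-resampling percentile bootstrap (or, optionally, a
delta-method approximation), accounting for the effect of sample size on
the reference range.  Values are classified five ways against the
resulting breakpoints: abnormal-low, indeterminate-low, normal,
indeterminate-high, abnormal-high.

Sex-stratified decade tables for the FD and global-strain metrics of a
healthy adult cohort (ages 20-69) ship with the package and can be used
directly for classification without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

MIN_N_PER_SEX = 10
MIN_AGE_SPAN = 20.0
MIN_BOOT = 200

LABELS = ["abnormal-low", "indeterminate-low", "normal", "indeterminate-high",
          "abnormal-high"]

SEXES = ("male", "female")


@dataclass
class SexModel:
    """Per-sex OLS fit of value on age, with the data kept for bootstrap."""

    slope: float
    intercept: float
    resid_sd: float
    n: int
    age_mean: float
    age_ss: float  # Sxx
    t_quantile: float
    ages: np.ndarray
    values: np.ndarray

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age

    def prediction_limits(self, age: float) -> tuple[float, float]:
        se = self.resid_sd * np.sqrt(
            1.0 + 1.0 / self.n + (age - self.age_mean) ** 2 / self.age_ss
        )
        mid = self.predict(age)
        return mid - self.t_quantile * se, mid + self.t_quantile * se


@dataclass
class ReferenceModel:
    """Sex-stratified age-dependent reference model for one metric."""

    metric: str
    units: str = ""
    models: dict[str, SexModel] = field(default_factory=dict)


@dataclass
class RangeRow:
    """One reference-range row: outer 95% prediction limits with their
    indeterminate (95% CI) pairs."""

    metric: str
    sex: str
    age_label: str
    lower_pair: tuple[float, float]
    mean: float
    upper_pair: tuple[float, float]


@dataclass
class Classification:
    label: str
    metric: str
    value: float
    sex: str
    age: float
    source: str  # "fitted model" | "packaged table"


def _fit_one_sex(ages: np.ndarray, values: np.ndarray) -> SexModel:
    n = ages.size
    if n < MIN_N_PER_SEX:
        raise ValidationError(f"need >= {MIN_N_PER_SEX} records per sex, got {n}")
    if np.ptp(ages) < MIN_AGE_SPAN:
        raise ValidationError(
            f"ages must span >= {MIN_AGE_SPAN} years, got {np.ptp(ages):.1f}"
        )
    xbar = float(ages.mean())
    sxx = float(np.sum((ages - xbar) ** 2))
    if sxx <= 0:
        raise ValidationError("degenerate age variance")
    b = float(np.sum((ages - xbar) * (values - values.mean())) / sxx)
    a = float(values.mean() - b * xbar)
    resid = values - (a + b * ages)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    s = max(s, np.finfo(float).eps)  # zero-noise cohorts collapse onto the line
    t = float(stats.t.ppf(0.975, n - 2))
    return SexModel(
        slope=b, intercept=a, resid_sd=s, n=n, age_mean=xbar, age_ss=sxx,
        t_quantile=t, ages=ages.copy(), values=values.copy(),
    )


def fit_reference(cohort: pd.DataFrame, metric: str, units: str = "") -> ReferenceModel:
    """Fit per-sex regressions of `value` on `age`.

    `cohort` needs columns age, sex ('male'/'female') and value.  A sex
    absent from the cohort is skipped with a warning.
    """
    required = {"age", "sex", "value"}
    if not required.issubset(cohort.columns):
        raise ValidationError(f"cohort must have columns {sorted(required)}")
    model = ReferenceModel(metric=metric, units=units)
    for sex in SEXES:
        sub = cohort[cohort["sex"] == sex]
        if sub.empty:
            warnings.warn(f"no {sex} records; model fitted only for the other sex")
            continue
        model.models[sex] = _fit_one_sex(
            sub["age"].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float)
        )
    if not model.models:
        raise ValidationError("cohort contains no male or female records")
    return model


def limits(
    model: ReferenceModel,
    sex: str,
    age: float,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "bootstrap",
) -> RangeRow:
    """Reference limits at a given age with indeterminate pairs.

    `method='bootstrap'`: case-resampling percentile bootstrap (2.5th and
    97.5th percentiles of each limit over `n_boot` refits, fixed seed).
    `method='delta'`: first-order analytic approximation.
    """
    if sex not in model.models:
        raise ValidationError(f"no fitted model for sex {sex!r}")
    sm = model.models[sex]
    span_lo, span_hi = sm.ages.min() - 10.0, sm.ages.max() + 10.0
    if not (span_lo <= age <= span_hi):
        raise ValidationError(
            f"age {age} outside fitted span [{sm.ages.min():.0f}, "
            f"{sm.ages.max():.0f}] +/- 10 years"
        )
    lo, hi = sm.prediction_limits(age)
    mid = sm.predict(age)

    if method == "bootstrap":
        if n_boot < MIN_BOOT:
            raise ValidationError(f"n_boot must be >= {MIN_BOOT}, got {n_boot}")
        rng = np.random.default_rng(seed)
        n = sm.n
        lows = np.empty(n_boot)
        highs = np.empty(n_boot)
        kept = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ages_b, vals_b = sm.ages[idx], sm.values[idx]
            if np.ptp(ages_b) <= 0:
                continue
            try:
                bm = _fit_one_sex_relaxed(ages_b, vals_b)
            except ValidationError:
                continue
            lows[kept], highs[kept] = bm.prediction_limits(age)
            kept += 1
        if kept < MIN_BOOT // 2:
            raise ValidationError("bootstrap failed: too many degenerate resamples")
        lower_pair = tuple(np.percentile(lows[:kept], [2.5, 97.5]))
        upper_pair = tuple(np.percentile(highs[:kept], [2.5, 97.5]))
    elif method == "delta":
        # Var(limit) ~= Var(yhat) + t^2 g Var(s-hat), with
        # Var(s-hat) ~= s^2 / (2(n-2)) under normal residuals
        g = 1.0 + 1.0 / sm.n + (age - sm.age_mean) ** 2 / sm.age_ss
        var_mean = sm.resid_sd**2 * (1.0 / sm.n + (age - sm.age_mean) ** 2 / sm.age_ss)
        var_s = sm.resid_sd**2 / (2.0 * (sm.n - 2))
        se_limit = float(np.sqrt(var_mean + sm.t_quantile**2 * g * var_s))
        z = float(stats.norm.ppf(0.975))
        lower_pair = (lo - z * se_limit, lo + z * se_limit)
        upper_pair = (hi - z * se_limit, hi + z * se_limit)
    else:
        raise ValidationError(f"unknown indeterminate-region method {method!r}")

    return RangeRow(
        metric=model.metric,
        sex=sex,
        age_label=f"{age:g}",
        lower_pair=(float(lower_pair[0]), float(lower_pair[1])),
        mean=float(mid),
        upper_pair=(float(upper_pair[0]), float(upper_pair[1])),
    )


def _fit_one_sex_relaxed(ages: np.ndarray, values: np.ndarray) -> SexModel:
    """Bootstrap refits skip the n/age-span preconditions of the public fit."""
    xbar = float(ages.mean())
    sxx = float(np.sum((ages - xbar) ** 2))
    if sxx <= 0:
        raise ValidationError("degenerate resample")
    n = ages.size
    b = float(np.sum((ages - xbar) * (values - values.mean())) / sxx)
    a = float(values.mean() - b * xbar)
    resid = values - (a + b * ages)
    s = max(float(np.sqrt(np.sum(resid**2) / (n - 2))), np.finfo(float).eps)
    t = float(stats.t.ppf(0.975, n - 2))
    return SexModel(b, a, s, n, xbar, sxx, t, ages, values)


# ---------------------------------------------------------------------------
# packaged decade tables


def load_reference_table() -> pd.DataFrame:
    """The packaged sex x age-decade reference rows (FD and strain metrics)."""
    with resources.files("lvfractal.data").joinpath("reference_ranges.csv").open() as fh:
        return pd.read_csv(fh)


def _decade_label(age: float) -> str:
    if not 20 <= age <= 69:
        raise ValidationError(
            f"packaged tables cover ages 20-69; got {age}"
        )
    lo = int(age) // 10 * 10
    return f"{lo}-{lo + 9}"


def table_row(metric: str, sex: str, age: float,
              table: pd.DataFrame | None = None) -> RangeRow:
    """Decade row from the packaged tables (used as-is, no interpolation)."""
    if table is None:
        table = load_reference_table()
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
    label = _decade_label(age)
    sub = table[(table["metric"] == metric) & (table["sex"] == sex)
                & (table["decade"] == label)]
    if sub.empty:
        raise ValidationError(f"no packaged row for {metric}/{sex}/{label}")
    r = sub.iloc[0]
    return RangeRow(
        metric=metric, sex=sex, age_label=label,
        lower_pair=(float(r["lower_lo"]), float(r["lower_hi"])),
        mean=float(r["mean"]),
        upper_pair=(float(r["upper_lo"]), float(r["upper_hi"])),
    )


def classify_row(row: RangeRow, value: float) -> str:
    """Five-way label for a value against one reference row.

    The row's lower->upper orientation is respected: for negative-signed
    strain metrics the 'upper' (abnormal-high) side is the more negative
    one, exactly as tabulated.
    """
    ll, lh = row.lower_pair
    ul, uh = row.upper_pair
    # orientation: +1 when the upper pair sits above the mean numerically
    direction = 1.0 if (ul + uh) / 2.0 >= row.mean else -1.0
    v = direction * value
    a, b = sorted((direction * ll, direction * lh))
    c, d = sorted((direction * ul, direction * uh))
    if v > d:
        return "abnormal-high"
    if v >= c:
        return "indeterminate-high"
    if v > b:
        return "normal"
    if v >= a:
        return "indeterminate-low"
    return "abnormal-low"


def classify(
    source: ReferenceModel | pd.DataFrame | None,
    metric: str,
    sex: str,
    age: float,
    value: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> Classification:
    """Classify a value against a fitted model or the packaged tables.

    Pass a ReferenceModel for the continuous-age path, or None / a table
    DataFrame for the packaged decade rows.
    """
    if isinstance(source, ReferenceModel):
        if source.metric != metric:
            raise ValidationError(
                f"model is for {source.metric!r}, not {metric!r}"
            )
        row = limits(source, sex, age, n_boot=n_boot, seed=seed)
        origin = "fitted model"
    else:
        row = table_row(metric, sex, age, table=source)
        origin = "packaged table"
    return Classification(
        label=classify_row(row, value), metric=metric, value=float(value),
        sex=sex, age=float(age), source=origin,
    )
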