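"""Reproducibility statistics: intraclass correlation.

Intra- and inter-observer agreement is quantified by the two-way
random-effects, absolute-agreement, single-measure intraclass correlation
coefficient, ICC(2,1).  From the two-way ANOVA mean squares (rows =
subjects, columns = raters):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the 95% confidence interval from the F-based approximation of
McGraw & Wong for this variant.  The averaged-measures form ICC(2,k) is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 5
MIN_RATERS = 2


@dataclass
class RatingMatrix:
    """n_subjects x k_raters measurement matrix, no missing cells."""

    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("rating matrix must be 2-D (subjects x raters)")
        n, k = self.values.shape
        if n < MIN_SUBJECTS or k < MIN_RATERS:
            raise ValidationError(
                f"need >= {MIN_SUBJECTS} subjects and >= {MIN_RATERS} raters, "
                f"got {n} x {k}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("rating matrix has missing cells; apply "
                                  "listwise deletion first")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    variant: str = "ICC(2,1) absolute agreement"


def ratings_from_long(df: pd.DataFrame, metric: str = "") -> RatingMatrix:
    """Pivot a long (subject_id, rater, value) table to a RatingMatrix.

    Subjects missing any rater are dropped (listwise deletion, logged).
    """
    wide = df.pivot(index="subject_id", columns="rater", values="value")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("listwise deletion dropped %d incomplete subjects", dropped)
    return RatingMatrix(values=complete.to_numpy(), metric=metric)


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    sse = np.sum((x - rows[:, None] - cols[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2way_random_agreement(
    m: RatingMatrix | np.ndarray,
    alpha: float = 0.05,
    average_measures: bool = False,
) -> ICCResult:
    """ICC(2,1) — or ICC(2,k) when `average_measures` — with a 95% CI."""
    if not isinstance(m, RatingMatrix):
        m = RatingMatrix(values=m)
    x = m.values
    n, k = m.n, m.k
    if float(x.std()) == 0.0:
        raise ValidationError("constant ratings: total variance is zero")
    msr, msc, mse = _mean_squares(x)

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc_single = (msr - mse) / denom_single

    # F-based CI for ICC(A,1) (McGraw & Wong 1996)
    r = icc_single
    a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    if not np.isfinite(num) or not np.isfinite(den) or den == 0.0:
        # degenerate (e.g. perfect agreement): interval collapses
        lo = hi = icc_single
    else:
        v = num / den
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = (n * (msr - f_l * mse)) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = (n * (f_u * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )

    if average_measures:
        icc_val = (msr - mse) / (msr + (msc - mse) / n)
        lo = lo * k / (1.0 + (k - 1.0) * lo) if np.isfinite(lo) else lo
        hi = hi * k / (1.0 + (k - 1.0) * hi) if np.isfinite(hi) else hi
        variant = f"ICC(2,{k}) absolute agreement"
    else:
        icc_val = icc_single
        variant = "ICC(2,1) absolute agreement"

    lo = float(min(lo, icc_val))
    hi = float(max(hi, icc_val))
    return ICCResult(icc=float(icc_val), ci_low=lo, ci_high=hi, n=n, k=k,
                     variant=variant)
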