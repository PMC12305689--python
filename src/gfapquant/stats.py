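"""Dose-response regression and hemisphere summaries.

The dose response is an ordinary least-squares fit of mean ROI GFAP+
fraction against prescription dose; the slope is tested against zero with
a two-sided Wald test using the t distribution with n - 2 degrees of
freedom (significance level 0.05), exactly the procedure of
``scipy.stats.linregress``.  Hemisphere summaries aggregate per-slice
right/left ROI means into per-dose-level mean +/- sample standard
deviation and paired right-minus-left differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DoseResponseFit",
    "HemisphereSummary",
    "fit_dose_response",
    "summarize_hemispheres",
]

ALPHA = 0.05


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS dose-response fit with Wald test of slope = 0."""

    slope: float  # fraction per Gy
    intercept: float  # fraction
    slope_se: float
    intercept_se: float
    p_value: float  # two-sided, t distribution with n - 2 df
    r_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if self.n < 3:
            raise ValueError("fit requires at least 3 points")

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        t_crit = sps.t.ppf(0.5 + level / 2.0, self.df)
        return (self.slope - t_crit * self.slope_se, self.slope + t_crit * self.slope_se)

    def to_dict(self) -> dict:
        return {
            "slope_per_Gy": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "p_value": self.p_value,
            "r_value": self.r_value,
            "n": self.n,
            "significant_at_0.05": self.significant,
        }


def fit_dose_response(doses, fractions) -> DoseResponseFit:
    """Linear least-squares fit of mean ROI fraction versus prescription dose.

    Requires at least three points and at least two distinct dose values.
    A constant response (zero residual variance around a zero slope) yields
    p = 1: the null of no dose effect cannot be rejected.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and fractions must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if np.unique(x).size < 2:
        raise ValueError("at least 2 distinct dose values are required (slope undefined)")
    res = sps.linregress(x, y)
    p = float(res.pvalue)
    if np.isnan(p):
        # constant y: slope 0 with zero residual variance
        p = 1.0
    return DoseResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        p_value=p,
        r_value=float(res.rvalue) if not np.isnan(res.rvalue) else 0.0,
        n=int(x.size),
    )


@dataclass
class HemisphereSummary:
    """Per-slice and per-dose-level summaries of right/left ROI fractions.

    ``per_slice`` has one row per slice with the paired right-minus-left
    difference; ``per_level`` has the mean and sample SD (ddof = 1; NaN
    for a single slice) of each hemisphere per prescription-dose level.
    """

    per_slice: pd.DataFrame
    per_level: pd.DataFrame


def summarize_hemispheres(per_slice: pd.DataFrame) -> HemisphereSummary:
    """Aggregate per-slice right/left ROI means by dose level.

    Parameters
    ----------
    per_slice : DataFrame
        Columns ``slice_id``, ``prescription_dose_Gy``, ``right_fraction``,
        ``left_fraction``.  Slices with a missing hemisphere value are
        excluded with a warning.
    """
    required = {"slice_id", "prescription_dose_Gy", "right_fraction", "left_fraction"}
    missing = required - set(per_slice.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = per_slice.copy()
    bad = df[["right_fraction", "left_fraction"]].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} slice(s) with a missing hemisphere value",
            stacklevel=2,
        )
        df = df[~bad]
    df = df.assign(right_minus_left=df["right_fraction"] - df["left_fraction"])
    per_level = (
        df.groupby("prescription_dose_Gy")
        .agg(
            right_mean=("right_fraction", "mean"),
            right_sd=("right_fraction", lambda s: s.std(ddof=1)),
            left_mean=("left_fraction", "mean"),
            left_sd=("left_fraction", lambda s: s.std(ddof=1)),
            n_slices=("slice_id", "count"),
        )
        .reset_index()
    )
    return HemisphereSummary(per_slice=df.reset_index(drop=True), per_level=per_level)
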