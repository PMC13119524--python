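"""Maximum specific growth rates from 24 h OD600 curves.

The estimator mirrors the classic sliding-window ("easy linear") heuristic:
ordinary least squares of ln(OD - blank) against time over every window of
``h`` consecutive points, keep windows whose fit is clean (R^2 >= 0.95), take
the steepest, merge neighbouring windows whose slope is within a quota of the
winner, and refit over the merged span.  Slopes are computed per minute
internally and reported per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "GrowthComparison",
    "EstimabilityError",
    "estimate_max_growth_rate",
    "compare_growth_rates",
]

_CLIP_EPS = 1e-4  # OD offset used when a value does not exceed the blank


class EstimabilityError(ValueError):
    """Too few usable points above the blank to fit a growth rate."""


@dataclass(frozen=True)
class GrowthCurve:
    """A 24 h microplate growth curve on a uniform 5-min grid."""

    isolate_id: str
    times_min: np.ndarray
    od600: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if times.ndim != 1 or times.shape != od.shape:
            raise ValueError("times and OD must be matching 1-d arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD600 values must be >= 0")
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Maximum specific growth rate with the window and fit that produced it."""

    isolate_id: str
    mumax: float          # h^-1
    window: tuple[int, int]  # inclusive point indices of the merged span
    r_squared: float
    n_points: int
    flags: tuple[str, ...] = ()


def _window_fits(t: np.ndarray, y: np.ndarray, h: int):
    """Vectorised OLS slope and R^2 for every window of h consecutive points."""
    n = len(t)
    n_win = n - h + 1
    idx = np.arange(h)[None, :] + np.arange(n_win)[:, None]
    tw, yw = t[idx], y[idx]
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    return slope, r2


def estimate_max_growth_rate(
    curve: GrowthCurve,
    h: int = 13,
    r2_min: float = 0.95,
    quota: float = 0.95,
) -> GrowthRateEstimate:
    """Sliding-window log-linear estimate of the maximum specific growth rate.

    Parameters
    ----------
    curve:
        Blank-corrected internally: values at or below the blank are clipped
        to ``blank + 1e-4`` before logging (flagged, not dropped, so the time
        grid stays uniform).
    h:
        Window size in points (>= 3).
    r2_min:
        Minimum window R^2 for a window to compete for the maximum slope; if
        no window qualifies the global maximum is used and flagged.
    quota:
        Windows overlapping the winner whose slope is >= quota * max-slope are
        merged and the span refitted.
    """
    if h < 3:
        raise ValueError("window size h must be >= 3")
    t = curve.times_min
    od = curve.od600
    flags: list[str] = []

    above = od > curve.blank
    if int(above.sum()) < h + 1:
        raise EstimabilityError(
            f"{curve.isolate_id}: only {int(above.sum())} points above the blank; "
            f"need at least {h + 1}"
        )
    corrected = od - curve.blank
    clipped = corrected <= 0
    if clipped.any():
        corrected = np.where(clipped, _CLIP_EPS, corrected)
        flags.append("clipped_below_blank")
    y = np.log(corrected)

    slope, r2 = _window_fits(t, y, h)
    qualified = r2 >= r2_min
    if clipped.any():
        # windows containing clipped placeholders cannot compete for the
        # maximum slope (the placeholder creates artificial jumps)
        has_clipped = np.convolve(clipped.astype(int), np.ones(h, dtype=int), "valid") > 0
        if not np.all(has_clipped):
            qualified &= ~has_clipped
    if not qualified.any():
        qualified = np.ones_like(qualified)
        flags.append("r2_fallback")
    masked = np.where(qualified, slope, -np.inf)
    i_star = int(np.argmax(masked))
    m_star = slope[i_star]

    # merge windows overlapping the winner whose slope meets the quota
    # (windows containing clipped placeholders never merge)
    n_win = len(slope)
    if clipped.any():
        blocked = np.convolve(clipped.astype(int), np.ones(h, dtype=int), "valid") > 0
    else:
        blocked = np.zeros(n_win, dtype=bool)
    threshold = quota * m_star if m_star > 0 else m_star / quota if m_star < 0 else m_star
    lo = hi = i_star
    j = i_star - 1
    while j >= 0 and i_star - j < h and slope[j] >= threshold and not blocked[j]:
        lo = j
        j -= 1
    j = i_star + 1
    while j < n_win and j - i_star < h and slope[j] >= threshold and not blocked[j]:
        hi = j
        j += 1
    span = (lo, hi + h - 1)  # inclusive point indices

    ts, ys = t[span[0] : span[1] + 1], y[span[0] : span[1] + 1]
    fit = sps.linregress(ts, ys)
    return GrowthRateEstimate(
        isolate_id=curve.isolate_id,
        mumax=float(fit.slope * 60.0),
        window=span,
        r_squared=float(fit.rvalue**2),
        n_points=span[1] - span[0] + 1,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class GrowthComparison:
    """One-way ANOVA across isolates plus per-isolate Welch tests vs. WT."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    table: pd.DataFrame
    flags: tuple[str, ...] = ()


def compare_growth_rates(
    rates: Mapping[str, Sequence[float]], wt_label: str = "WT"
) -> GrowthComparison:
    """Compare replicate growth-rate estimates among isolates.

    One-way fixed-effects ANOVA over all groups, then pairwise Welch t tests
    of each isolate against the wild type with Holm adjustment.  All-constant
    input yields a flagged result with undefined F.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in rates.items()}
    if len(groups) < 2:
        raise ValueError("need at least two isolate groups")
    if wt_label not in groups:
        raise ValueError(f"wild-type group {wt_label!r} missing")
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} needs >= 2 replicates")

    flags: list[str] = []
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        f_stat, p_val = math.nan, math.nan
        flags.append("zero_variance")
    else:
        f_stat, p_val = sps.f_oneway(*groups.values())
    df_between = len(groups) - 1
    df_within = len(pooled) - len(groups)

    wt = groups[wt_label]
    rows = []
    for label, values in groups.items():
        if label == wt_label:
            continue
        if np.allclose(values, values[0]) and np.allclose(wt, wt[0]):
            t, p = math.nan, math.nan
        else:
            t, p = sps.ttest_ind(values, wt, equal_var=False)
        rows.append(
            {
                "isolate_id": label,
                "n": len(values),
                "mean": values.mean(),
                "diff_vs_wt": values.mean() - wt.mean(),
                "t": t,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    valid = table["p_raw"].notna()
    table["p_holm"] = np.nan
    if valid.any():
        table.loc[valid, "p_holm"] = multipletests(
            table.loc[valid, "p_raw"], method="holm"
        )[1]
    return GrowthComparison(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        df_between=df_between,
        df_within=df_within,
        table=table,
        flags=tuple(flags),
    )
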