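"""Growth-curve kinetics: exponential-phase regression and strain comparisons.

Doubling times come from linear regression of log10-transformed OD600 on
time over an automatically selected exponential window (R^2 >= 0.95 by
default); lag time is where that regression line reaches the t = 0
log10-OD; cultures with no OD increase over at least a six-month horizon
are called no-growth; strain comparisons use a two-sided t-test assuming
unequal variance (Welch).

Window selection is deterministic: a window qualifies when it has at least
``min_window`` points, positive slope, R^2 >= ``r2_min``, and every
contiguous sub-window of ``min_window`` points also clears the same slope
and R^2 bar (the window must look exponential locally, not just on
average — this keeps windows from creeping into lag or stationary phases
whose few off-trend points a long window's R^2 would forgive). Among
qualifying windows the longest wins; ties go to the steepest slope, then
the earliest start.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GrowthDataError

logger = logging.getLogger(__name__)

LOG10_2 = math.log10(2.0)

#: Six months, in hours: the observation horizon for a no-growth call.
SIX_MONTHS_H = 4320.0


@dataclass
class GrowthCurve:
    """OD600 time series for one replicate of one strain."""

    strain: str
    replicate: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD600, positive (blank-subtracted upstream)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise GrowthDataError(
                f"{self.strain}/{self.replicate}: times and od must be "
                "equal-length 1-D arrays"
            )
        if len(self.times) < 3:
            raise GrowthDataError(
                f"{self.strain}/{self.replicate}: need >= 3 points"
            )
        if np.any(np.diff(self.times) <= 0):
            raise GrowthDataError(
                f"{self.strain}/{self.replicate}: times must be strictly increasing"
            )
        if np.any(self.od <= 0) or not np.all(np.isfinite(self.od)):
            raise GrowthDataError(
                f"{self.strain}/{self.replicate}: OD values must be positive "
                "and finite (blank subtraction happens upstream)"
            )


@dataclass
class GrowthFit:
    """Exponential-window regression result for one curve."""

    status: str  # growth, no_growth, indeterminate
    slope: float = float("nan")  # log10-OD per hour
    intercept: float = float("nan")  # log10-OD
    r2: float = float("nan")
    window: tuple[int, int] | None = None  # inclusive index range used
    T_D: float = float("nan")  # doubling time, hours
    T_Lag: float = float("nan")  # lag time, hours


@dataclass
class WelchResult:
    """Two-sided t-test assuming unequal variance."""

    t: float
    df: float
    p: float


def _window_stats(t: np.ndarray, y: np.ndarray, i: int, j: int):
    """OLS slope, intercept and R^2 on the inclusive window [i, j]."""
    tw = t[i : j + 1]
    yw = y[i : j + 1]
    n = len(tw)
    tbar = tw.mean()
    ybar = yw.mean()
    stt = float(np.sum((tw - tbar) ** 2))
    sty = float(np.sum((tw - tbar) * (yw - ybar)))
    syy = float(np.sum((yw - ybar) ** 2))
    if stt == 0.0:
        return 0.0, ybar, float("nan")
    slope = sty / stt
    intercept = ybar - slope * tbar
    if syy == 0.0:
        # perfectly flat response: define R^2 = 1 only if residuals are 0
        return slope, intercept, 1.0 if sty == 0.0 else 0.0
    r2 = (sty * sty) / (stt * syy)
    return slope, intercept, r2


def fit_exponential(
    curve: GrowthCurve, r2_min: float = 0.95, min_window: int = 4
) -> GrowthFit:
    """Select the exponential window and regress log10-OD on time.

    Returns ``status='growth'`` with slope, R^2, T_D = log10(2)/slope and
    the window used, or ``status='indeterminate'`` when no window
    qualifies (degenerate and linear-growth curves land here).
    """
    t = curve.times
    y = np.log10(curve.od)
    n = len(t)
    w = min_window
    if n < w:
        return GrowthFit(status="indeterminate")
    # local exponentiality: every min_window sub-window must clear the bar
    sub_ok = np.zeros(n - w + 1, dtype=bool)
    for s in range(n - w + 1):
        slope, _, r2 = _window_stats(t, y, s, s + w - 1)
        sub_ok[s] = slope > 0 and r2 >= r2_min
    ok_prefix = np.concatenate(([0], np.cumsum(sub_ok)))
    best: tuple[int, float, int] | None = None  # (length, slope, -start)
    best_fit: GrowthFit | None = None
    for i in range(n - w + 1):
        for j in range(i + w - 1, n):
            n_sub = (j - w + 1) - i + 1  # sub-windows inside [i, j]
            if ok_prefix[j - w + 2] - ok_prefix[i] != n_sub:
                continue
            slope, intercept, r2 = _window_stats(t, y, i, j)
            if not (slope > 0 and r2 >= r2_min):
                continue
            key = (j - i + 1, slope, -i)
            if best is None or key > best:
                best = key
                best_fit = GrowthFit(
                    status="growth",
                    slope=slope,
                    intercept=intercept,
                    r2=r2,
                    window=(i, j),
                    T_D=LOG10_2 / slope,
                )
    if best_fit is None:
        return GrowthFit(status="indeterminate")
    return best_fit


def lag_time(fit: GrowthFit, curve: GrowthCurve) -> float:
    """Hours where the exponential regression line meets the t = 0 log10-OD.

    ``T_Lag = (log10(od at t=0) - intercept) / slope``. When the curve
    has no point at exactly t = 0 the earliest point stands in (logged).
    """
    if fit.status != "growth":
        raise GrowthDataError("lag_time requires a fit with status='growth'")
    if not fit.slope > 0:
        raise GrowthDataError("lag_time requires a positive slope")
    if curve.times[0] == 0.0:
        y0 = math.log10(curve.od[0])
    else:
        logger.info(
            "%s/%s: no t=0 point; using earliest point t=%.3g h as proxy",
            curve.strain,
            curve.replicate,
            curve.times[0],
        )
        y0 = math.log10(curve.od[0])
    return (y0 - fit.intercept) / fit.slope


def call_no_growth(
    curve: GrowthCurve,
    min_delta: float = 0.05,
    horizon: float = SIX_MONTHS_H,
    r2_min: float = 0.95,
    min_window: int = 4,
) -> str:
    """No-growth call, deferring to the exponential fit otherwise.

    ``no_growth`` iff the OD never rises ``min_delta`` above its starting
    value AND the observed span covers at least ``horizon`` hours (six
    months by default). A flat curve observed for less than the horizon
    is indeterminate, not no-growth.
    """
    increase = float(curve.od.max() - curve.od[0])
    span = float(curve.times[-1] - curve.times[0])
    if increase < min_delta:
        if span >= horizon:
            return "no_growth"
        return "indeterminate"
    return fit_exponential(curve, r2_min=r2_min, min_window=min_window).status


def analyze_curve(
    curve: GrowthCurve,
    r2_min: float = 0.95,
    min_window: int = 4,
    min_delta: float = 0.05,
    horizon: float = SIX_MONTHS_H,
) -> GrowthFit:
    """Full per-curve analysis: no-growth gate, fit, then lag time."""
    increase = float(curve.od.max() - curve.od[0])
    span = float(curve.times[-1] - curve.times[0])
    if increase < min_delta and span >= horizon:
        return GrowthFit(status="no_growth")
    fit = fit_exponential(curve, r2_min=r2_min, min_window=min_window)
    if fit.status == "growth":
        fit.T_Lag = lag_time(fit, curve)
    return fit


def welch_t(x, y) -> WelchResult:
    """Two-sided t-test assuming unequal variance (Welch).

    ``t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y)`` with
    Welch–Satterthwaite degrees of freedom; p is the two-sided tail of
    the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise GrowthDataError("welch_t requires >= 2 observations per sample")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    dm = float(np.mean(x) - np.mean(y))
    if vx == 0.0 and vy == 0.0:
        warnings.warn(
            "both samples have zero variance; p set by convention",
            stacklevel=2,
        )
        if dm == 0.0:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        return WelchResult(
            t=math.copysign(float("inf"), dm), df=float(nx + ny - 2), p=0.0
        )
    se2 = vx / nx + vy / ny
    t = dm / math.sqrt(se2)
    df = se2 * se2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=min(p, 1.0))


# ---------------------------------------------------------------------------
# Table I/O


def read_curves_csv(path) -> list[GrowthCurve]:
    """Read curves from a CSV with columns strain, replicate, time_h, od600."""
    frame = pd.read_csv(path)
    required = {"strain", "replicate", "time_h", "od600"}
    missing = required - set(frame.columns)
    if missing:
        raise GrowthDataError(f"{path}: missing column(s) {sorted(missing)}")
    curves = []
    for (strain, replicate), grp in frame.groupby(
        ["strain", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                replicate=str(replicate),
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy(),
            )
        )
    return curves


def fits_to_frame(curves: list[GrowthCurve], fits: list[GrowthFit]) -> pd.DataFrame:
    rows = []
    for curve, fit in zip(curves, fits):
        rows.append(
            {
                "strain": curve.strain,
                "replicate": curve.replicate,
                "status": fit.status,
                "slope": fit.slope,
                "r2": fit.r2,
                "window_start": fit.window[0] if fit.window else -1,
                "window_end": fit.window[1] if fit.window else -1,
                "T_D_h": fit.T_D,
                "T_Lag_h": fit.T_Lag,
            }
        )
    return pd.DataFrame(rows)


def compare_strains(
    frame: pd.DataFrame, strain_a: str, strain_b: str, metric: str
) -> WelchResult:
    """Welch comparison of a per-replicate metric (T_D_h or T_Lag_h)."""
    grown = frame[frame["status"] == "growth"]
    x = grown.loc[grown["strain"] == strain_a, metric].to_numpy()
    y = grown.loc[grown["strain"] == strain_b, metric].to_numpy()
    return welch_t(x, y)
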