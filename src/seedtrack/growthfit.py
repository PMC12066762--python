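"""Germination time and early growth rate from leaf-area time series.

Arabidopsis cotyledon growth is expansion-dominated and close to linear
for the first days after emergence; exponential growth only starts with
the first true leaf pair.  The early phase is therefore identified by
backward elimination: starting from the full series, trailing points
are removed one at a time until a linear fit satisfies all of

* adjusted R² > 0.9,
* slope and intercept each significantly different from 0
  (two-sided t-test, α = 0.05 by default),
* deviance (residual sum of squares) / number of points < 0.1.

The slope of the accepted fit is the early growth rate (mm²/d) and the
x-axis intercept is the germination time (days after sowing).  An
exponential curve ``A(t) = A₀·exp(r·t)`` is additionally fitted to all
points from emergence onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from skimage.color import rgb2hsv

from .errors import DomainError

__all__ = [
    "LeafAreaSeries",
    "GrowthFit",
    "FitCriteria",
    "green_area",
    "detect_emergence",
    "fit_linear_segment",
    "fit_exponential",
]

#: area of one top-view imaging pixel; 10 green pixels = 0.013 mm²
DEFAULT_PIXEL_AREA_MM2 = 0.0013
#: a seedling counts as emerged at this many green pixels
EMERGENCE_THRESHOLD_PX = 10


@dataclass
class LeafAreaSeries:
    """Per-pot projected leaf-area time series.

    times are days after sowing (strictly increasing); areas (mm²) are
    derived from green-pixel counts via ``pixel_area``.
    """

    times: np.ndarray
    green_pixels: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA_MM2
    seed_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.green_pixels = np.asarray(self.green_pixels)
        if self.pixel_area <= 0:
            raise DomainError("pixel_area must be positive")
        if len(self.times) != len(self.green_pixels):
            raise DomainError("times and green_pixels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")

    @property
    def areas(self) -> np.ndarray:
        return self.green_pixels * self.pixel_area


@dataclass
class FitCriteria:
    """Acceptance gates for the backward-elimination linear fit."""

    adj_r2_min: float = 0.9
    alpha: float = 0.05
    deviance_per_n_max: float = 0.1
    min_points: int = 4


@dataclass
class GrowthFit:
    """Results container for one pot's growth analysis."""

    status: str  # fitted | no-emergence | no-linear-fit
    germination_time: float | None = None  # d
    growth_rate: float | None = None  # mm²/d
    linear_segment: tuple[int, int] | None = None  # index range into series
    slope: float | None = None
    intercept: float | None = None
    adj_r2: float | None = None
    deviance_per_n: float | None = None
    slope_p: float | None = None
    intercept_p: float | None = None
    exp_params: tuple[float, float] | None = None  # (A0, r)
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        if self.status != "fitted":
            return f"GrowthFit(status={self.status})"
        return (
            f"GrowthFit(status=fitted, germination_time={self.germination_time:.2f} d, "
            f"growth_rate={self.growth_rate:.3f} mm²/d, adj_r2={self.adj_r2:.3f}, "
            f"deviance/n={self.deviance_per_n:.4f}, segment={self.linear_segment})"
        )


# HSV gates for "green" pixels; hue in degrees of the full 360° circle
GREEN_HUE_RANGE = (60.0, 180.0)
GREEN_SAT_MIN = 0.25
GREEN_VAL_MIN = 0.15


def green_area(
    pot_image: np.ndarray,
    pixel_area: float = DEFAULT_PIXEL_AREA_MM2,
) -> tuple[int, float]:
    """Count green (plant) pixels in an RGB pot crop and convert to mm².

    A pixel is green when its HSV hue falls in the green band and both
    saturation and value clear minimal gates (soil is dull, walls are
    grey — neither is saturated green).  Zero is a valid result.
    """
    img = np.asarray(pot_image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise DomainError("expected an RGB image")
    hsv = rgb2hsv(img[..., :3])
    hue_deg = hsv[..., 0] * 360.0
    green = (
        (hue_deg >= GREEN_HUE_RANGE[0]) & (hue_deg <= GREEN_HUE_RANGE[1])
        & (hsv[..., 1] > GREEN_SAT_MIN) & (hsv[..., 2] > GREEN_VAL_MIN)
    )
    count = int(green.sum())
    return count, count * pixel_area


def detect_emergence(
    series: LeafAreaSeries, threshold_px: int = EMERGENCE_THRESHOLD_PX
) -> float | None:
    """First time the green-pixel count reaches the emergence threshold.

    Germination is defined operationally as optical detectability: the
    first observation with at least ``threshold_px`` green pixels
    (10 px ≈ 0.013 mm²).  Returns None if the threshold is never met.
    """
    hits = np.nonzero(series.green_pixels >= threshold_px)[0]
    if hits.size == 0:
        return None
    return float(series.times[hits[0]])


def _linear_fit_stats(t: np.ndarray, a: np.ndarray):
    """OLS of area on time; returns (slope, intercept, adj_r2, rss, p_slope, p_int)."""
    X = sm.add_constant(t)
    res = sm.OLS(a, X).fit()
    intercept, slope = res.params
    rss = float(res.ssr)
    if rss < 1e-14:  # numerically perfect line: p-values are 0 by convention
        return slope, intercept, 1.0, rss, 0.0, 0.0
    return slope, intercept, float(res.rsquared_adj), rss, float(res.pvalues[1]), float(res.pvalues[0])


def fit_linear_segment(
    series: LeafAreaSeries,
    criteria: FitCriteria = FitCriteria(),
    emergence_threshold_px: int = EMERGENCE_THRESHOLD_PX,
) -> GrowthFit:
    """Backward-elimination linear fit of the early growth phase.

    Leading zero-area observations are dropped; the fit then starts
    from the full remaining series and removes exactly one trailing
    point per iteration until every acceptance gate holds (so the
    accepted segment is the longest qualifying prefix).  The x-axis
    intercept of the accepted line is the germination time (clamped at
    0 with a flag if negative) and its slope the early growth rate.
    """
    fit = GrowthFit(status="no-emergence")
    if detect_emergence(series, emergence_threshold_px) is None:
        return fit

    nz = np.nonzero(series.areas > 0)[0]
    start = int(nz[0])
    t = series.times[start:]
    a = series.areas[start:]

    for end in range(len(t), criteria.min_points - 1, -1):
        slope, intercept, adj_r2, rss, p_slope, p_int = _linear_fit_stats(t[:end], a[:end])
        dev_n = rss / end
        if (
            adj_r2 > criteria.adj_r2_min
            and p_slope < criteria.alpha
            and p_int < criteria.alpha
            and dev_n < criteria.deviance_per_n_max
            and slope > 0
        ):
            germ = -intercept / slope
            flags = []
            if germ < 0:
                germ = 0.0
                flags.append("negative_x_intercept_clamped")
            fit = GrowthFit(
                status="fitted",
                germination_time=float(germ),
                growth_rate=float(slope),
                linear_segment=(start, start + end),
                slope=float(slope),
                intercept=float(intercept),
                adj_r2=adj_r2,
                deviance_per_n=float(dev_n),
                slope_p=p_slope,
                intercept_p=p_int,
                flags=flags,
            )
            break
    else:
        return GrowthFit(status="no-linear-fit")

    try:
        fit.exp_params = fit_exponential(series)
    except (DomainError, RuntimeError):
        fit.flags.append("exponential_fit_failed")
    return fit


def fit_exponential(series: LeafAreaSeries) -> tuple[float, float]:
    """Least-squares fit of A(t) = A₀·exp(r·t) from emergence onward.

    Initialized from a log-linear regression on the positive areas.
    ``r`` is expected nonnegative for growing plants but its sign is
    not enforced.
    """
    nz = np.nonzero(series.areas > 0)[0]
    if nz.size < 3:
        raise DomainError("need at least 3 positive-area points")
    t = series.times[nz[0]:]
    a = series.areas[nz[0]:]
    pos = a > 0
    r0, loga0 = np.polyfit(t[pos], np.log(a[pos]), 1)

    def model(tt, a0, r):
        return a0 * np.exp(r * tt)

    (a0, r), _ = curve_fit(model, t, a, p0=[np.exp(loga0), r0], maxfev=10000)
    return float(a0), float(r)
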