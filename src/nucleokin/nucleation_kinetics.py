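"""From crystal-count time series to steady-state areal nucleation rates.

The raw kinetic observable is a cumulative count of crystallites inside an
optical window of known area, time-stamped in minutes.  The rate J0 is the
slope of crystal *density* (counts / window area, m^-2) versus time (s) over
the linear portion of the record, mirroring how flow-cell nucleation assays
are analysed: an induction/burn-in transient is discarded, the longest
contiguous window that is statistically linear is selected, and an ordinary
least-squares slope with its standard error is reported in SI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, RegimeNotFoundError, ValidationError

MM2_TO_M2 = 1e-6
MIN_TO_S = 60.0

DEFAULT_MIN_POINTS = 4
DEFAULT_R2_THRESHOLD = 0.95
DEFAULT_BURN_IN_MIN = 10.0


@dataclass(frozen=True)
class CountTimeSeries:
    """Cumulative crystallite counts in one viewing window.

    times : minutes since flow start (strictly increasing)
    counts : cumulative counts (non-negative, non-decreasing integers)
    window_area : mm^2 (6.13 or 1.53 for the 50x / 100x magnifications)
    sigma : supersaturation of the experiment
    """

    times: tuple[float, ...]
    counts: tuple[int, ...]
    window_area: float
    sigma: float
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.size != c.size:
            raise ValidationError("times and counts must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        if t.size and np.any(np.diff(c) < 0):
            raise ValidationError(
                "cumulative counts must be non-decreasing (each crystal is "
                "assumed to persist once nucleated)"
            )
        if self.window_area <= 0:
            raise DomainError(f"window_area must be > 0, got {self.window_area}")


@dataclass(frozen=True)
class RateEstimate:
    """Steady-state areal nucleation rate from one count series."""

    j0: float                     # nuclei m^-2 s^-1
    j0_se: float
    regime: tuple[int, int]       # [start, end) indices into the fitted arrays
    r_squared: float
    n_points: int
    negative_slope: bool = False  # physical fits have j0 >= 0; flagged, not clipped


def counts_to_density(series: CountTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Convert to SI: times in seconds, density in nuclei per m^2."""
    t_s = np.asarray(series.times, dtype=float) * MIN_TO_S
    density = np.asarray(series.counts, dtype=float) / (series.window_area * MM2_TO_M2)
    return t_s, density


def _window_r2(px, py, pxx, pxy, pyy, i, j):
    """R^2 of the OLS line over [i, j) from prefix sums; flat data -> 1."""
    n = j - i
    sx = px[j] - px[i]
    sy = py[j] - py[i]
    sxx = pxx[j] - pxx[i]
    sxy = pxy[j] - pxy[i]
    syy = pyy[j] - pyy[i]
    ss_xx = sxx - sx * sx / n
    ss_yy = syy - sy * sy / n
    ss_xy = sxy - sx * sy / n
    if ss_yy <= 0:
        return 1.0  # constant y fits a (zero-slope) line exactly
    return ss_xy * ss_xy / (ss_xx * ss_yy)


def detect_linear_regime(
    times: np.ndarray,
    density: np.ndarray,
    min_points: int = DEFAULT_MIN_POINTS,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> tuple[int, int]:
    """Longest contiguous window whose OLS fit has R^2 >= threshold.

    Ties at equal length are broken toward the earliest start.  Returns the
    half-open index window ``(start, stop)``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(density, dtype=float)
    n = t.size
    if n < min_points:
        raise InsufficientDataError(
            f"need at least min_points={min_points} samples, got {n}"
        )
    z = np.zeros(1)
    px = np.concatenate([z, np.cumsum(t)])
    py = np.concatenate([z, np.cumsum(y)])
    pxx = np.concatenate([z, np.cumsum(t * t)])
    pxy = np.concatenate([z, np.cumsum(t * y)])
    pyy = np.concatenate([z, np.cumsum(y * y)])

    best_r2 = -np.inf
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            r2 = _window_r2(px, py, pxx, pxy, pyy, start, start + length)
            if r2 >= r2_threshold:
                return start, start + length
            best_r2 = max(best_r2, r2)
    raise RegimeNotFoundError(
        f"no window of >= {min_points} points reached R^2 >= {r2_threshold} "
        f"(best R^2 = {best_r2:.4f})",
        best_r2=best_r2,
    )


def estimate_J0(
    series: CountTimeSeries,
    *,
    burn_in_min: float = DEFAULT_BURN_IN_MIN,
    min_points: int = DEFAULT_MIN_POINTS,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    weighted: bool = False,
) -> RateEstimate:
    """OLS slope of crystal density vs time over the detected linear regime.

    ``burn_in_min`` drops samples earlier than the stated time (the initial
    high-flow-rate period); ``weighted`` switches to Poisson (1/count)
    weights, off by default to match plain-OLS treatment of such data.
    """
    t_s, density = counts_to_density(series)
    keep = np.asarray(series.times, dtype=float) >= burn_in_min
    t_s, density = t_s[keep], density[keep]
    start, stop = detect_linear_regime(t_s, density, min_points, r2_threshold)
    x, y = t_s[start:stop], density[start:stop]

    if weighted:
        counts = np.asarray(series.counts, dtype=float)[keep][start:stop]
        w = 1.0 / np.maximum(counts, 1.0)
        slope, slope_se, r2 = _wls_slope(x, y, w)
    else:
        fit = stats.linregress(x, y)
        slope, r2 = fit.slope, fit.rvalue**2
        slope_se = _cumulative_slope_se(x, y)

    return RateEstimate(
        j0=float(slope),
        j0_se=float(slope_se),
        regime=(int(start), int(stop)),
        r_squared=float(r2),
        n_points=int(stop - start),
        negative_slope=bool(slope < 0),
    )


def _cumulative_slope_se(x: np.ndarray, y: np.ndarray) -> float:
    """Standard error of the OLS slope for cumulative counting data.

    Cumulative counts are a sum of independent increments, so regression
    errors are a random walk, not iid noise; the usual residual-based OLS
    standard error understates the slope uncertainty several-fold.  This
    sandwich form uses Cov(y_i, y_j) = lam * min(t_i, t_j) with the
    increment-variance rate ``lam`` estimated by moments from the observed
    increments.  On noise-free linear data the increments are exactly
    proportional to the time steps, lam = 0 and the SE is exactly 0; on a
    Poisson process lam is consistent for the event rate, making a 3-SE
    interval hold at its nominal level.
    """
    n = x.size
    if n < 2:
        return np.nan
    dt = np.diff(x)
    dy = np.diff(y)
    rate = np.sum(dy) / np.sum(dt)
    lam = np.sum((dy - rate * dt) ** 2) / np.sum(dt)
    xc = x - x.mean()
    w = xc / np.sum(xc * xc)            # OLS slope = w . y
    t0 = x[0]
    cov = lam * (np.minimum.outer(x, x) - t0)
    var = float(w @ cov @ w)
    return float(np.sqrt(max(var, 0.0)))


def _wls_slope(x, y, w):
    """Weighted least squares slope with standard error (unit-weight scale)."""
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    dof = max(x.size - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    se = np.sqrt(s2 / sxx)
    ss_tot = np.sum(w * (y - yb) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    return slope, se, r2
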