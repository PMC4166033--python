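"""Whisker kinematics and vibration-signal spectra.

Kinematics follow the tracked-point convention of high-speed whisker
videography: a cubic spline is fit through the tracked points of each
frame, resampled densely, and first/second backward differences give the
base angle theta_base = arctan(ydot_2 / xdot_2) and the discrete curvature
kappa_n = |xdot ydotdot - ydot xdotdot| / (xdot^2 + ydot^2)^(3/2), with
kappa_max the per-frame maximum.  Slip-stick events are high-acceleration
excursions of the whisker trace.  Vibration voltage signals are
characterized by their Welch power spectral density on a 128-bin grid and
its power centroid C = sum S(f) f / sum S(f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

N_PSD_BINS = 128
SPLINE_RESAMPLE = 200  # points along the whisker after spline interpolation


@dataclass
class WhiskerGeometry:
    theta_base: float  # radians
    kappa: np.ndarray  # per resampled point; NaN where undefined
    kappa_max: float
    points: np.ndarray  # resampled (N, 2)


def _resample_spline(points: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline interpolation of the tracked points, resampled at n
    equally spaced arc-length (chord-length) positions."""
    p = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(p, axis=0).T)
    if np.any(seg == 0):
        raise ValueError("coincident consecutive tracked points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    cs_x = CubicSpline(s, p[:, 0])
    cs_y = CubicSpline(s, p[:, 1])
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([cs_x(si), cs_y(si)])


def whisker_geometry(points: np.ndarray, resample: int = SPLINE_RESAMPLE) -> WhiskerGeometry:
    """Base angle and discrete curvature of one frame's whisker.

    ``points`` are ordered base to tip (>= 4 required).  Derivatives are
    backward differences on the spline-resampled chain; points with zero
    first-derivative magnitude are excluded from the curvature maximum
    with a warning.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 4 or p.shape[1] != 2:
        raise ValueError("need >= 4 ordered 2-D points")
    q = _resample_spline(p, resample)
    xd = np.diff(q[:, 0])  # xdot_n, n = 2..N
    yd = np.diff(q[:, 1])
    xdd = np.diff(xd)      # xdotdot_n, n = 3..N
    ydd = np.diff(yd)
    theta_base = float(np.arctan2(yd[0], xd[0]))

    denom = (xd[1:] ** 2 + yd[1:] ** 2) ** 1.5
    kappa = np.full(resample, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.abs(xd[1:] * ydd - yd[1:] * xdd) / denom
    bad = denom == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} points with zero tangent excluded from curvature")
        k[bad] = np.nan
    kappa[2:] = k
    kmax = float(np.nanmax(kappa)) if np.any(np.isfinite(kappa)) else np.nan
    return WhiskerGeometry(theta_base=theta_base, kappa=kappa, kappa_max=kmax, points=q)


@dataclass
class SlipStickResult:
    low_count: int
    high_count: int
    low_rate: float   # events / second
    high_rate: float
    ratio: float      # high / low
    accelerations: np.ndarray  # |a| at detected event peaks


def acceleration(x: np.ndarray, dt: float) -> np.ndarray:
    """Central second difference of a position/angle series, in
    (position units) per (time unit)^2."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("series shorter than 3 samples")
    return (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2


def slip_stick_events(
    x: np.ndarray,
    dt: float,
    low_band: tuple[float, float] = (4.0, 9.0),
    high_min: float = 28.0,
) -> SlipStickResult:
    """Count slip-stick events in a whisker position trace.

    An event is a local maximum of absolute acceleration.  Low events
    fall inside ``low_band`` (default 4-9 position-units/ms^2 when the
    series is sampled in ms), high events at or above ``high_min``.
    Rates are per second of trace; ratio is high/low.
    """
    a = np.abs(acceleration(x, dt))
    peaks, _ = sps.find_peaks(a)
    pa = a[peaks]
    low = int(np.sum((pa >= low_band[0]) & (pa < low_band[1])))
    high = int(np.sum(pa >= high_min))
    dur = (len(x) - 1) * dt
    return SlipStickResult(
        low_count=low,
        high_count=high,
        low_rate=low / dur,
        high_rate=high / dur,
        ratio=high / low if low > 0 else np.inf if high > 0 else np.nan,
        accelerations=pa,
    )


def event_counts_above(x: np.ndarray, dt: float, thresholds: np.ndarray) -> np.ndarray:
    """Cumulative event counts: events with peak |acceleration| above each
    threshold (monotonically non-increasing in the threshold)."""
    a = np.abs(acceleration(x, dt))
    peaks, _ = sps.find_peaks(a)
    pa = a[peaks]
    return np.array([int(np.sum(pa > th)) for th in np.asarray(thresholds, dtype=float)])


def welch_psd(
    v: np.ndarray,
    rate: float,
    n_bins: int = N_PSD_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch averaged-periodogram PSD on exactly ``n_bins`` one-sided
    frequency bins (Hann window, 50% overlap)."""
    v = np.asarray(v, dtype=float)
    nperseg = 2 * (n_bins - 1)
    if v.size < nperseg:
        raise ValueError(f"signal too short for {n_bins} PSD bins (need >= {nperseg} samples)")
    f, s = sps.welch(v, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    return f, s


def power_centroid(v: np.ndarray, rate: float, n_bins: int = N_PSD_BINS) -> float:
    """Power centroid C = sum_m S(f_m) f_m / sum_m S(f_m) over the
    ``n_bins``-bin Welch PSD, in Hz."""
    f, s = welch_psd(v, rate, n_bins)
    total = s.sum()
    if total <= 0:
        raise ValueError("power centroid undefined for an all-zero signal")
    return float(np.sum(s * f) / total)
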