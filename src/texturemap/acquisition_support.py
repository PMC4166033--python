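"""Free-hand line-scan timing and image-drift quality control.

The free-hand line scan visits a user-drawn list of pixel positions each
cycle; its period is n * dwellTime plus the slower of the two galvo
return times, and the scan frequency is the reciprocal.  Recording
stability is monitored by FFT-based cross-correlation of each trial's
image against a time-averaged template: the correlation peak position
gives the integer pixel shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft, signal as sps


@dataclass(frozen=True)
class ScanPath:
    """Ordered scanned pixel positions with galvo timing parameters."""

    x: np.ndarray  # pixels
    y: np.ndarray
    dwell_time: float      # seconds per pixel
    x_galvo_speed: float   # pixels per second, return movement
    y_galvo_speed: float

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ValueError("path needs >= 2 (x, y) positions")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.x_galvo_speed <= 0 or self.y_galvo_speed <= 0:
            raise ValueError("galvo speeds must be positive")


def scan_timing(path: ScanPath) -> tuple[float, float]:
    """(single-line-scan period in s, scan frequency in Hz).

    period = n * dwellTime + max(X-return-time, Y-return-time) with
    X-return-time = |X_n - X_1| / X-galvo-speed (Y analogous): the beam
    retraces the straight line between the scan endpoints at the galvo
    return speed.
    """
    n = len(path.x)
    x_return = abs(path.x[-1] - path.x[0]) / path.x_galvo_speed
    y_return = abs(path.y[-1] - path.y[0]) / path.y_galvo_speed
    period = n * path.dwell_time + max(x_return, y_return)
    return float(period), float(1.0 / period)


def template_image(stack: np.ndarray) -> np.ndarray:
    """Time-averaged reference image of a (T, H, W) trial stack."""
    s = np.asarray(stack, dtype=float)
    if s.ndim != 3:
        raise ValueError("expected a (time, height, width) stack")
    return s.mean(axis=0)


def measure_shift(
    template: np.ndarray,
    trial: np.ndarray,
    circular: bool = False,
) -> tuple[int, int]:
    """Integer (dx, dy) displacement of ``trial`` relative to ``template``.

    Cross-correlation is computed in the frequency domain and the
    correlation-peak position read off; positive dx/dy means the trial
    image is displaced toward +x/+y.  Zero-padded (linear) correlation is
    the default; ``circular=True`` wraps around instead.

    Raises
    ------
    ValueError
        For mismatched shapes or structureless (constant) images.
    """
    a = np.asarray(template, dtype=float)
    b = np.asarray(trial, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("template and trial must be equal-sized 2-D images")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant image: shift undefined")
    a = a - a.mean()
    b = b - b.mean()
    if circular:
        corr = fft.ifft2(fft.fft2(b) * np.conj(fft.fft2(a))).real
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        h, w = a.shape
        dy = iy - h if iy > h // 2 else iy
        dx = ix - w if ix > w // 2 else ix
    else:
        corr = sps.fftconvolve(b, a[::-1, ::-1], mode="full")
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        dy = iy - (a.shape[0] - 1)
        dx = ix - (a.shape[1] - 1)
    return int(dx), int(dy)
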