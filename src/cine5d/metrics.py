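"""Image-quality metrics (SSIM, PSNR) for comparing reconstructions.

Complex series are compared by magnitude, the standard convention for MRI
quality reporting.  SSIM follows the original formulation: per-frame 3D
comparison with a Gaussian window (sigma = 1.5, 11-voxel support, truncated
symmetrically when a volume is smaller than the window), constants K1 = 0.01
and K2 = 0.03, population (not sample) window statistics, and the data range
taken from the reference argument.  Local statistics are computed with
Gaussian filters and the score is averaged over the valid interior region
(no padding influence), then over frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from cine5d.data_model import ImageSeries5D

__all__ = ["QualityReport", "ssim", "psnr", "quality_report", "save_report"]

_SIGMA = 1.5
_MAX_RADIUS = 5  # 11-voxel window
_K1 = 0.01
_K2 = 0.03


@dataclass
class QualityReport:
    """Mean SSIM/PSNR of a reconstruction against a reference, with per-frame detail."""

    ssim: float
    psnr_db: float
    frames: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"ssim": self.ssim, "psnr_db": self.psnr_db, "frames": self.frames},
            indent=2,
            default=lambda v: "inf" if v == math.inf else v,
        )


def _magnitudes(a: ImageSeries5D, b: ImageSeries5D) -> tuple[np.ndarray, np.ndarray]:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    return np.abs(a.data), np.abs(b.data)


def _window_radius(grid: tuple[int, ...]) -> int:
    # largest radius whose (2r+1)-window fits the smallest volume dimension
    r = min(_MAX_RADIUS, (min(grid) - 1) // 2)
    if r < 1:
        raise ValueError(f"volume too small for windowed SSIM: grid {grid}")
    return r


def ssim_volume(x: np.ndarray, y: np.ndarray, data_range: float, radius: int | None = None) -> float:
    """Gaussian-windowed SSIM of two real 3D volumes."""
    if radius is None:
        radius = _window_radius(x.shape)
    truncate = radius / _SIGMA
    filt = {"sigma": _SIGMA, "truncate": truncate, "mode": "reflect"}
    x = x.astype(np.float64, copy=False)
    y = y.astype(np.float64, copy=False)
    ux = gaussian_filter(x, **filt)
    uy = gaussian_filter(y, **filt)
    uxx = gaussian_filter(x * x, **filt)
    uyy = gaussian_filter(y * y, **filt)
    uxy = gaussian_filter(x * y, **filt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    interior = tuple(slice(radius, n - radius) for n in x.shape)
    return float(s[interior].mean())


def ssim(a: ImageSeries5D, b: ImageSeries5D) -> float:
    """Mean over frames of 3D Gaussian-windowed SSIM of magnitudes.

    ``b`` is the reference: the data range is its magnitude peak-to-peak,
    shared across frames so per-frame values are comparable.
    """
    mag_a, mag_b = _magnitudes(a, b)
    data_range = float(mag_b.max() - mag_b.min()) or 1.0
    radius = _window_radius(a.grid)
    vals = [
        ssim_volume(mag_a[i, j], mag_b[i, j], data_range, radius)
        for i in range(a.nr)
        for j in range(a.nc)
    ]
    return float(np.mean(vals))


def psnr(a: ImageSeries5D, b: ImageSeries5D) -> float:
    """10 log10(peak^2 / MSE) in dB, peak = max magnitude of the reference b.

    Identical inputs report infinity (zero error), not an error.
    """
    mag_a, mag_b = _magnitudes(a, b)
    mse = float(np.mean((mag_a - mag_b) ** 2))
    if mse == 0.0:
        return math.inf
    peak = float(mag_b.max())
    return 10.0 * math.log10(peak * peak / mse)


def quality_report(a: ImageSeries5D, b: ImageSeries5D) -> QualityReport:
    """Per-frame and mean SSIM/PSNR of ``a`` against reference ``b``."""
    mag_a, mag_b = _magnitudes(a, b)
    data_range = float(mag_b.max() - mag_b.min()) or 1.0
    radius = _window_radius(a.grid)
    peak = float(mag_b.max())
    frames = []
    for i in range(a.nr):
        for j in range(a.nc):
            s = ssim_volume(mag_a[i, j], mag_b[i, j], data_range, radius)
            mse = float(np.mean((mag_a[i, j] - mag_b[i, j]) ** 2))
            p = math.inf if mse == 0 or peak == 0 else 10 * math.log10(peak**2 / mse)
            # 1-based phase indices, respiratory first
            frames.append({"i": i + 1, "j": j + 1, "ssim": s, "psnr_db": p})
    return QualityReport(
        ssim=float(np.mean([f["ssim"] for f in frames])),
        psnr_db=psnr(a, b),
        frames=frames,
    )


def save_report(report: QualityReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())
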