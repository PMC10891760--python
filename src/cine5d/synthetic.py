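"""Synthetic 5D cardiac/respiratory phantom, coil maps, masks and noise.

The generator emulates the experimental setup the reconstruction targets: a
numerically simulated beating, breathing torso imaged with a multicoil
Cartesian acquisition, retrospectively undersampled with a variable-density
(ky, kz) pattern at a stated acceleration factor, with optional complex
Gaussian noise at a stated SNR.  Defaults follow the target acquisition:
20 cardiac phases, 4 respiratory phases (80 volumes), 16 coils reducible for
desk-scale work (the bundled desk-scale preset uses a 32x32x8 grid with
4 coils).

Everything is a deterministic function of the spec and its seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from cine5d.data_model import (
    CoilSet,
    ImageSeries5D,
    KSpace5D,
    write_container,
)
from cine5d.operators import apply_encoding

__all__ = [
    "PhantomSpec",
    "MaskSpec",
    "generate_phantom",
    "generate_coils",
    "generate_masks",
    "simulate_acquisition",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class PhantomSpec:
    """Geometry and motion of the analytic phantom.

    ``cardiac_contraction_fraction`` is the peak fractional shrinkage of the
    heart radii over the cardiac cycle (peak contraction at mid-cycle);
    ``respiratory_shift_voxels`` the peak-to-peak sinusoidal z-translation of
    the heart over the respiratory cycle.
    """

    grid: tuple[int, int, int] = (32, 32, 8)
    nc: int = 20
    nr: int = 4
    ncoils: int = 4
    cardiac_contraction_fraction: float = 0.3
    respiratory_shift_voxels: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nc < 2:
            raise ValueError(f"need Nc >= 2 cardiac phases, got {self.nc}")
        if self.nr < 1:
            raise ValueError(f"need Nr >= 1 respiratory phases, got {self.nr}")
        if any(g < 4 for g in self.grid):
            raise ValueError(f"grid dims must be >= 4, got {self.grid}")
        if not 0.0 < self.cardiac_contraction_fraction < 1.0:
            raise ValueError(
                f"cardiac_contraction_fraction must lie in (0, 1), "
                f"got {self.cardiac_contraction_fraction}"
            )
        if self.ncoils < 1:
            raise ValueError(f"need >= 1 coil, got {self.ncoils}")


@dataclass
class MaskSpec:
    """Undersampling pattern parameters.

    ``af`` is the acceleration factor (full / acquired samples; 4, 8 and 10
    are the usual presets, any value >= 1 is accepted); ``center_fraction``
    the fully sampled central (ky, kz) disc as a fraction of the plane.
    """

    af: float = 4.0
    center_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.af < 1:
            raise ValueError(f"acceleration factor must be >= 1, got {self.af}")
        if not 0.0 <= self.center_fraction < 1.0:
            raise ValueError(
                f"center_fraction must lie in [0, 1), got {self.center_fraction}"
            )


def _soft_ellipsoid(
    grid: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    edge: float = 0.08,
) -> np.ndarray:
    """Smooth indicator of an ellipsoid (sigmoid edge softens Gibbs ringing)."""
    nx, ny, nz = grid
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    rho = np.sqrt(
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    )
    return 1.0 / (1.0 + np.exp((rho - 1.0) / edge))


def generate_phantom(spec: PhantomSpec) -> ImageSeries5D:
    """Analytic ground-truth series: a torso with a beating, breathing heart.

    Deterministic per (spec, i, j): a static torso ellipsoid and spine rod,
    plus a heart shell and blood pool whose radii shrink sinusoidally over
    the cardiac cycle (peak contraction at mid-cycle) and whose centre
    translates along z sinusoidally over the respiratory cycle.  A smooth
    complex phase ramp mimics off-resonance/coil loading phase.
    """
    nx, ny, nz = spec.grid
    frames = np.empty((spec.nr, spec.nc, nx, ny, nz), dtype=np.complex128)
    torso = 0.5 * _soft_ellipsoid(
        spec.grid,
        center=((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2),
        radii=(0.45 * nx, 0.42 * ny, 0.48 * nz),
    )
    spine = 0.35 * _soft_ellipsoid(
        spec.grid,
        center=((nx - 1) / 2, 0.82 * ny, (nz - 1) / 2),
        radii=(0.08 * nx, 0.08 * ny, 0.48 * nz),
        edge=0.12,
    )
    xg, yg = np.ogrid[0:nx, 0:ny]
    phase = np.exp(1j * (0.5 * np.pi * xg / nx + 0.3 * np.pi * yg / ny))[..., None]
    heart_r0 = (0.22 * nx, 0.2 * ny, 0.3 * nz)
    for i in range(spec.nr):
        # periodic respiratory displacement of the heart along z
        resp = 0.5 * spec.respiratory_shift_voxels * (1.0 - math.cos(2.0 * math.pi * i / spec.nr))
        for j in range(spec.nc):
            # contraction peaks at mid cardiac cycle
            scale = 1.0 - spec.cardiac_contraction_fraction * math.sin(math.pi * j / spec.nc) ** 2
            center = (0.42 * nx, 0.38 * ny, (nz - 1) / 2 + resp)
            radii = tuple(r * scale for r in heart_r0)
            shell = _soft_ellipsoid(spec.grid, center, radii)
            pool = _soft_ellipsoid(spec.grid, center, tuple(0.6 * r for r in radii))
            vol = torso + spine + 0.6 * shell - 0.25 * pool
            frames[i, j] = vol * phase
    return ImageSeries5D(data=frames, voxel_size_mm=(2.0, 2.0, 2.0))


def generate_coils(spec: PhantomSpec) -> CoilSet:
    """Smooth complex coil sensitivities, normalized to unit sum-of-squares.

    Gaussian magnitude profiles centred on points around the field of view,
    each with its own linear phase ramp; after normalization
    sum_c |S_c|^2 = 1 at every voxel.
    """
    nx, ny, nz = spec.grid
    n = spec.ncoils
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    maps = np.empty((n, nx, ny, nz), dtype=np.complex128)
    sigma2 = (0.6 * max(nx, ny)) ** 2
    for c in range(n):
        ang = 2.0 * math.pi * c / n
        cx = (nx - 1) / 2 + 0.6 * nx * math.cos(ang) / 2
        cy = (ny - 1) / 2 + 0.6 * ny * math.sin(ang) / 2
        cz = (nz - 1) / 2 + 0.2 * nz * math.cos(2 * ang) / 2
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / (2 * sigma2)))
        ramp = 0.3 * math.pi * (math.cos(ang) * x / nx + math.sin(ang) * y / ny) + ang / 3
        maps[c] = mag * np.exp(1j * ramp)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos
    return CoilSet(maps=maps)


def _frame_mask(
    ny: int, nz: int, spec: MaskSpec, frame_seed: tuple[int, ...]
) -> np.ndarray:
    """One (ky, kz) sampling pattern with an exact per-frame sample budget."""
    n_plane = ny * nz
    n_target = max(1, round(n_plane / spec.af))
    ky, kz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    # centred, normalized k-space radius in the phase-encode plane
    r = np.sqrt(
        ((ky - (ny - 1) / 2) / (ny / 2)) ** 2 + ((kz - (nz - 1) / 2) / (nz / 2)) ** 2
    )
    center = r <= math.sqrt(spec.center_fraction)
    mask = center.copy()
    n_remaining = n_target - int(mask.sum())
    if n_remaining > 0:
        outside = np.flatnonzero(~mask.ravel())
        # variable density: sampling probability decays with k-space radius
        weights = np.exp(-2.0 * r.ravel()[outside] ** 2)
        weights /= weights.sum()
        rng = np.random.default_rng(frame_seed)
        chosen = rng.choice(outside, size=min(n_remaining, outside.size), replace=False, p=weights)
        flat = mask.ravel()
        flat[chosen] = True
        mask = flat.reshape(ny, nz)
    return mask


def generate_masks(
    grid: tuple[int, int, int], nc: int, nr: int, spec: MaskSpec
) -> np.ndarray:
    """Per-frame binary sampling masks, shape (Nr, Nc, Nx, Ny, Nz).

    The readout axis (kx) is fully sampled; each frame's (ky, kz) plane gets
    a fully sampled central disc plus variable-density random samples whose
    density decays with k-space radius.  The per-frame sample budget is set
    exactly, so the sampled fraction matches 1/af up to integer rounding.
    Patterns are seeded per frame index: identical seeds reproduce identical
    masks, different frames get different patterns.
    """
    nx, ny, nz = grid
    if spec.af == 1.0:
        return np.ones((nr, nc, nx, ny, nz), dtype=np.uint8)
    masks = np.empty((nr, nc, nx, ny, nz), dtype=np.uint8)
    for i in range(nr):
        for j in range(nc):
            plane = _frame_mask(ny, nz, spec, (spec.seed, i, j))
            masks[i, j] = np.broadcast_to(plane[None, :, :], (nx, ny, nz))
    return masks


def simulate_acquisition(
    truth: ImageSeries5D,
    coils: CoilSet,
    masks: np.ndarray,
    snr_db: float = math.inf,
    seed: int = 0,
    reference_power: float | None = None,
) -> KSpace5D:
    """Encode the ground truth and add complex Gaussian noise at a target SNR.

    SNR is defined over sampled k-space entries:
    10 log10(mean |y|^2 / noise power) = snr_db.  ``snr_db = inf`` adds no
    noise.  A zero (or empty) signal needs ``reference_power`` to set the
    noise scale; without one it is an error.
    """
    y = apply_encoding(truth, coils, masks)
    if math.isinf(snr_db):
        return y
    sampled = np.broadcast_to(masks.astype(bool)[:, :, None], y.data.shape)
    n_sampled = int(sampled.sum())
    signal_power = float(np.sum(np.abs(y.data[sampled]) ** 2)) / n_sampled
    if signal_power == 0.0:
        if reference_power is None:
            raise ValueError(
                "cannot scale noise for an all-zero signal without reference_power"
            )
        signal_power = float(reference_power)
    noise_power = signal_power * 10.0 ** (-snr_db / 10.0)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(noise_power / 2.0)
    noise = sigma * (
        rng.standard_normal(n_sampled) + 1j * rng.standard_normal(n_sampled)
    )
    data = y.data.copy()
    data[sampled] += noise
    return KSpace5D(data=data, masks=np.asarray(masks, dtype=np.uint8))


def generate_dataset(
    phantom_spec: PhantomSpec,
    mask_spec: MaskSpec,
    snr_db: float = math.inf,
) -> tuple[KSpace5D, CoilSet, ImageSeries5D]:
    """Full synthetic pipeline: phantom, coils, masks, (noisy) acquisition."""
    truth = generate_phantom(phantom_spec)
    coils = generate_coils(phantom_spec)
    masks = generate_masks(phantom_spec.grid, phantom_spec.nc, phantom_spec.nr, mask_spec)
    kspace = simulate_acquisition(truth, coils, masks, snr_db, seed=phantom_spec.seed)
    return kspace, coils, truth


def write_dataset(
    path: str | Path,
    phantom_spec: PhantomSpec,
    mask_spec: MaskSpec,
    snr_db: float = math.inf,
) -> None:
    """Generate a dataset and write it as a container including the reference."""
    kspace, coils, truth = generate_dataset(phantom_spec, mask_spec, snr_db)
    attrs = {"af": float(mask_spec.af), "seed": int(phantom_spec.seed)}
    if not math.isinf(snr_db):
        attrs["snr_db"] = float(snr_db)
    write_container(path, kspace, coils, reference=truth, attrs=attrs)
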