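"""Domain types and the HDF5 container shared by all reconstruction stages.

Array layout convention (fixed; violating shapes are rejected, never
transposed): the respiratory phase ``i`` is the slowest phase axis, the
cardiac phase ``j`` the next one, so a 5D image series is indexed
``(i, j, x, y, z)`` and k-space ``(i, j, coil, kx, ky, kz)``.  Phase indices
are 0-based in code; user-facing messages report them 1-based, matching the
common m_{i,j} notation for frame (respiratory i, cardiac j).

All complex arrays are complex128 (64-bit per component).  The tight
agreement demanded between partitioned and global reconstructions leaves no
room for single precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "ContainerError",
    "ImageSeries5D",
    "KSpace5D",
    "CoilSet",
    "ReconConfig",
    "ObjectiveHistory",
    "read_container",
    "write_container",
    "export_nifti_frames",
]

COMPLEX_DTYPE = np.complex128


class ContainerError(ValueError):
    """A container file or in-memory object violates the layout contract.

    Carries ``dataset``, the HDF5 path (or field name) of the offending data.
    """

    def __init__(self, message: str, dataset: str | None = None):
        self.dataset = dataset
        if dataset is not None:
            message = f"{message} (dataset: {dataset})"
        super().__init__(message)


def _as_complex(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a), dtype=COMPLEX_DTYPE)


@dataclass
class ImageSeries5D:
    """A 5D image series: complex 3D volumes over respiratory x cardiac phases.

    ``data`` is indexed ``(i, j, x, y, z)`` with ``i`` the respiratory phase
    (Nr values) and ``j`` the cardiac phase (Nc values).  Temporal total
    variation along the cardiac axis requires Nc >= 2.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _as_complex(self.data)
        if self.data.ndim != 5:
            raise ContainerError(
                f"image series must be 5D (i, j, x, y, z), got shape {self.data.shape}",
                dataset="image.data",
            )
        if self.nr < 1 or self.nc < 2:
            raise ContainerError(
                f"need Nr >= 1 and Nc >= 2 cardiac phases for temporal TV, "
                f"got Nr={self.nr}, Nc={self.nc}",
                dataset="image.data",
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)  # type: ignore[assignment]

    @classmethod
    def _unchecked(cls, data: np.ndarray) -> "ImageSeries5D":
        # internal fast path: caller guarantees the invariants
        obj = object.__new__(cls)
        obj.data = data
        obj.voxel_size_mm = (1.0, 1.0, 1.0)
        return obj

    @property
    def nr(self) -> int:
        return self.data.shape[0]

    @property
    def nc(self) -> int:
        return self.data.shape[1]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[2:]


@dataclass
class KSpace5D:
    """Acquired multicoil Cartesian k-space with its per-frame sampling masks.

    ``data`` is indexed ``(i, j, coil, kx, ky, kz)``; ``masks`` is a binary
    array ``(i, j, kx, ky, kz)`` shared by all coils of a frame.  Data must be
    zero wherever the frame mask is zero: the encoding operator's range
    includes the sampling matrix.
    """

    data: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        self.data = _as_complex(self.data)
        masks = np.asarray(self.masks)
        if self.data.ndim != 6:
            raise ContainerError(
                f"k-space must be 6D (i, j, coil, kx, ky, kz), got shape {self.data.shape}",
                dataset="kspace.data",
            )
        if masks.ndim != 5:
            raise ContainerError(
                f"masks must be 5D (i, j, kx, ky, kz), got shape {masks.shape}",
                dataset="kspace.mask",
            )
        expected = self.data.shape[:2] + self.data.shape[3:]
        if masks.shape != expected:
            raise ContainerError(
                f"mask shape {masks.shape} does not match k-space frames {expected}",
                dataset="kspace.mask",
            )
        if not np.isin(masks, (0, 1)).all():
            raise ContainerError("masks must be binary (0/1)", dataset="kspace.mask")
        self.masks = np.ascontiguousarray(masks, dtype=np.uint8)
        unsampled = np.broadcast_to(self.masks[:, :, None] == 0, self.data.shape)
        if np.any(self.data[unsampled] != 0):
            raise ContainerError(
                "k-space holds nonzero values at masked-out locations",
                dataset="kspace.data",
            )

    @classmethod
    def _unchecked(cls, data: np.ndarray, masks: np.ndarray) -> "KSpace5D":
        # internal fast path: caller guarantees the invariants
        obj = object.__new__(cls)
        obj.data = data
        obj.masks = masks
        return obj

    @property
    def nr(self) -> int:
        return self.data.shape[0]

    @property
    def nc(self) -> int:
        return self.data.shape[1]

    @property
    def ncoils(self) -> int:
        return self.data.shape[2]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[3:]


@dataclass
class CoilSet:
    """Complex coil sensitivity maps, indexed ``(coil, x, y, z)``.

    Maps are stored already normalized: sum_c |S_c|^2 <= 1 everywhere (the
    generator normalizes; the reader only validates).  This makes the
    encoding operator's norm bound ||E||^2 <= 1 hold by construction.
    """

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = _as_complex(self.maps)
        if self.maps.ndim != 4:
            raise ContainerError(
                f"coil maps must be 4D (coil, x, y, z), got shape {self.maps.shape}",
                dataset="coils.maps",
            )
        sos = np.sum(np.abs(self.maps) ** 2, axis=0)
        if sos.max() > 1.0 + 1e-6:
            raise ContainerError(
                f"coil maps are not normalized: max sum-of-squares {sos.max():.6g} > 1",
                dataset="coils.maps",
            )

    @property
    def ncoils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass
class ObjectiveHistory:
    """Objective values f(m^k) recorded per iteration within one solver stage."""

    values: list[float] = field(default_factory=list)
    stage_index: int = 1

    def append(self, value: float) -> None:
        value = float(value)
        if not np.isfinite(value) or value < 0:
            raise ValueError(
                f"objective must be finite and nonnegative, got {value} "
                f"at stage {self.stage_index}, iteration {len(self.values) + 1}"
            )
        self.values.append(value)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ReconConfig:
    """Solver and partitioning configuration.

    Parameters
    ----------
    lambda_reg:
        Regularization weight λ; ``None`` selects the data-scaled default
        0.01 · max |E^H y| at run time.
    n_stages, max_iter_per_stage, tau, tol:
        Stage count (μ-continuation), per-stage iteration cap, minimum
        iterations before the progress-quotient stopping rule activates, and
        the stopping tolerance on that quotient.
    mu_final:
        Final (smallest) Huber smoothing width; ``None`` selects μ0 · 1e-3.
    seed:
        Seed for any stochastic component of a run.
    n_devices, device_capacities, manual_split:
        Simulated-device count, relative capacity weights, and an optional
        explicit list of cardiac-phase counts overriding the partitioner.
    exec_mode:
        ``single`` (unpartitioned), ``lockstep`` (deterministic round-robin
        devices) or ``concurrent`` (threaded devices).
    local_stopping:
        If True each device stops on its own local progress quotient; if
        False the stopping statistic is the global objective, forcing equal
        iteration counts on all devices.
    ttv_weights:
        Per-axis (cardiac, respiratory) weights of the temporal-TV transform.
    """

    lambda_reg: float | None = None
    n_stages: int = 4
    max_iter_per_stage: int = 100
    tau: int = 7
    tol: float = 1e-5
    mu_final: float | None = None
    mu_decay_mode: str = "geometric"
    seed: int = 0
    n_devices: int = 1
    device_capacities: Sequence[float] | None = None
    manual_split: Sequence[int] | None = None
    exec_mode: str = "single"
    local_stopping: bool = True
    ttv_weights: tuple[float, float] = (1.0, 1.0)
    barrier_timeout_s: float = 300.0

    def __post_init__(self) -> None:
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ValueError(f"lambda_reg must be nonnegative, got {self.lambda_reg}")
        if self.n_stages < 1:
            raise ValueError(f"n_stages must be >= 1, got {self.n_stages}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.max_iter_per_stage < self.tau:
            raise ValueError(
                f"max_iter_per_stage ({self.max_iter_per_stage}) must be >= tau ({self.tau})"
            )
        if self.tol < 0:
            raise ValueError(f"tol must be nonnegative, got {self.tol}")
        if self.mu_final is not None and self.mu_final <= 0:
            raise ValueError(f"mu_final must be positive, got {self.mu_final}")
        if self.mu_decay_mode != "geometric":
            raise ValueError(f"unknown mu_decay_mode {self.mu_decay_mode!r}")
        if self.n_devices < 1:
            raise ValueError(f"n_devices must be >= 1, got {self.n_devices}")
        if self.exec_mode not in ("single", "lockstep", "concurrent"):
            raise ValueError(f"unknown exec_mode {self.exec_mode!r}")
        if self.device_capacities is not None:
            caps = [float(c) for c in self.device_capacities]
            if len(caps) != self.n_devices:
                raise ValueError(
                    f"device_capacities has {len(caps)} entries for {self.n_devices} devices"
                )
            if any(c <= 0 for c in caps):
                raise ValueError("device capacities must be positive")
            self.device_capacities = caps
        if any(w < 0 for w in self.ttv_weights):
            raise ValueError("ttv_weights must be nonnegative")


# ---------------------------------------------------------------------------
# HDF5 container
#
# /kspace/data    complex128, (Nr, Nc, Ncoils, Nx, Ny, Nz)
# /kspace/mask    uint8 {0,1}, (Nr, Nc, Nx, Ny, Nz)
# /coils/maps     complex128, (Ncoils, Nx, Ny, Nz)
# /reference/data complex128, (Nr, Nc, Nx, Ny, Nz)   [optional]
# /recon/data     complex128, (Nr, Nc, Nx, Ny, Nz)   [optional]
# root attributes: af, voxel_size_mm, and optionally seed, snr_db
# ---------------------------------------------------------------------------

_DSETS = {
    "kspace_data": "/kspace/data",
    "kspace_mask": "/kspace/mask",
    "coil_maps": "/coils/maps",
    "reference": "/reference/data",
    "recon": "/recon/data",
}


def _write_dset(f: h5py.File, path: str, array: np.ndarray) -> None:
    # track_times=False keeps dataset bytes independent of wall-clock time
    f.create_dataset(path, data=array, track_times=False)


def write_container(
    path: str | Path,
    kspace: KSpace5D,
    coils: CoilSet,
    reference: ImageSeries5D | None = None,
    recon: ImageSeries5D | None = None,
    attrs: dict | None = None,
) -> None:
    """Write k-space, coil maps and optional image series to an HDF5 file.

    Writing is deterministic: identical inputs produce identical dataset
    contents (no timestamps are stored).
    """
    if kspace.grid != coils.grid:
        raise ContainerError(
            f"k-space grid {kspace.grid} does not match coil grid {coils.grid}",
            dataset=_DSETS["coil_maps"],
        )
    with h5py.File(path, "w") as f:
        _write_dset(f, _DSETS["kspace_data"], kspace.data)
        _write_dset(f, _DSETS["kspace_mask"], kspace.masks)
        _write_dset(f, _DSETS["coil_maps"], coils.maps)
        voxel = (1.0, 1.0, 1.0)
        for series, key in ((reference, "reference"), (recon, "recon")):
            if series is not None:
                if series.data.shape != (kspace.nr, kspace.nc, *kspace.grid):
                    raise ContainerError(
                        f"{key} shape {series.data.shape} does not match k-space "
                        f"frames ({kspace.nr}, {kspace.nc}, {kspace.grid})",
                        dataset=_DSETS[key],
                    )
                _write_dset(f, _DSETS[key], series.data)
                voxel = series.voxel_size_mm
        f.attrs["voxel_size_mm"] = np.asarray(voxel, dtype=np.float64)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def _require(f: h5py.File, path: str) -> h5py.Dataset:
    node = f.get(path)
    if node is None:
        raise ContainerError("missing dataset", dataset=path)
    return node


def read_container(
    path: str | Path,
) -> tuple[KSpace5D, CoilSet, ImageSeries5D | None, dict]:
    """Read a container; returns (kspace, coils, reference-or-None, attrs).

    All type invariants are validated; any violation raises
    :class:`ContainerError` naming the offending dataset.  A stored
    reconstruction, if present, is returned under the ``"recon"`` attrs key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        ks_data = _require(f, _DSETS["kspace_data"])[...]
        ks_mask = _require(f, _DSETS["kspace_mask"])[...]
        maps = _require(f, _DSETS["coil_maps"])[...]
        if ks_data.ndim != 6:
            raise ContainerError(
                f"expected 6D k-space, got shape {ks_data.shape}",
                dataset=_DSETS["kspace_data"],
            )
        if ks_mask.ndim != 5:
            raise ContainerError(
                f"expected 5D masks (i, j, kx, ky, kz), got shape {ks_mask.shape}",
                dataset=_DSETS["kspace_mask"],
            )
        attrs = dict(f.attrs)
        voxel = tuple(attrs.pop("voxel_size_mm", (1.0, 1.0, 1.0)))
        try:
            kspace = KSpace5D(data=ks_data, masks=ks_mask)
            coils = CoilSet(maps=maps)
        except ContainerError:
            raise
        if coils.grid != kspace.grid:
            raise ContainerError(
                f"coil grid {coils.grid} does not match k-space grid {kspace.grid}",
                dataset=_DSETS["coil_maps"],
            )
        reference = None
        for key, out in (("reference", True), ("recon", False)):
            node = f.get(_DSETS[key])
            if node is None:
                continue
            series = ImageSeries5D(data=node[...], voxel_size_mm=voxel)
            if series.data.shape != (kspace.nr, kspace.nc, *kspace.grid):
                raise ContainerError(
                    f"{key} shape {series.data.shape} inconsistent with k-space",
                    dataset=_DSETS[key],
                )
            if out:
                reference = series
            else:
                attrs["recon"] = series
    return kspace, coils, reference, attrs


def export_nifti_frames(series: ImageSeries5D, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Export per-frame magnitude volumes as NIfTI files (one per (i, j))."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*series.voxel_size_mm, 1.0])
    paths = []
    for i in range(series.nr):
        for j in range(series.nc):
            img = nib.Nifti1Image(np.abs(series.data[i, j]).astype(np.float32), affine)
            # 1-based phase indices in filenames, matching the m_{i,j} notation
            p = out_dir / f"{prefix}_r{i + 1:02d}_c{j + 1:02d}.nii"
            nib.save(img, p)
            paths.append(p)
    return paths
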