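"""Encoding and regularization operators of the CS reconstruction.

The objective is

    f(m) = 1/2 ||E m - y||_2^2 + lambda * f_mu(Phi m)

where ``E`` applies, per frame (i, j) and coil c, the coil sensitivity, an
orthonormal 3D DFT and the binary sampling mask; ``Phi`` takes non-circular
finite differences along the cardiac and respiratory phase axes (temporal
total variation, tTV); and ``f_mu`` is the Huber smoothing of the l1 norm.
With normalized coil maps and the orthonormal DFT, ||E||^2 <= 1 and
||Phi||^2 <= 4 (w_c^2 + w_r^2), so the gradient's Lipschitz constant is
available in closed form (used by the solver).

The gradient of the regularizer, Lambda = Phi^H f_mu'(Phi m), couples each
frame only to its four phase neighbours (i, j+-1) and (i+-1, j).  That
locality is what makes ghost-frame exchange sufficient when the cardiac axis
is partitioned across devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from cine5d.data_model import CoilSet, ImageSeries5D, KSpace5D

__all__ = [
    "TTVDiffs",
    "HuberParams",
    "apply_encoding",
    "apply_encoding_adjoint",
    "ttv_forward",
    "ttv_adjoint",
    "huber_value",
    "huber_grad",
    "objective",
    "gradient",
    "objective_and_gradient",
    "phi_norm_sq_bound",
]

_SPATIAL_AXES = (-3, -2, -1)


@dataclass
class TTVDiffs:
    """Forward temporal differences of a 5D series.

    ``cardiac[i, j] = m[i, j+1] - m[i, j]`` (Nc-1 cardiac slots) and
    ``respiratory[i, j] = m[i+1, j] - m[i, j]`` (Nr-1 respiratory slots);
    differences are non-circular (no wrap from the last phase to the first).
    """

    cardiac: np.ndarray
    respiratory: np.ndarray

    def max_abs(self) -> float:
        m = float(np.abs(self.cardiac).max()) if self.cardiac.size else 0.0
        if self.respiratory.size:
            m = max(m, float(np.abs(self.respiratory).max()))
        return m


@dataclass
class HuberParams:
    """Smoothing width mu of the Huber approximation to |.|."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def _check_shapes(m: np.ndarray, coils: CoilSet, masks: np.ndarray) -> None:
    if m.shape[2:] != coils.grid:
        raise ValueError(f"image grid {m.shape[2:]} != coil grid {coils.grid}")
    if masks.shape != m.shape[:2] + m.shape[2:]:
        raise ValueError(f"mask shape {masks.shape} inconsistent with image {m.shape}")


def apply_encoding(m: ImageSeries5D, coils: CoilSet, masks: np.ndarray) -> KSpace5D:
    """E m: per frame and coil, mask * F(S_c * m_{i,j}) with orthonormal DFT."""
    _check_shapes(m.data, coils, masks)
    # (Nr, Nc, 1, x, y, z) * (coil, x, y, z) -> (Nr, Nc, coil, x, y, z)
    weighted = m.data[:, :, None] * coils.maps
    k = scipy.fft.fftn(weighted, axes=_SPATIAL_AXES, norm="ortho")
    k *= masks[:, :, None]
    return KSpace5D._unchecked(k, np.asarray(masks, dtype=np.uint8))


def apply_encoding_adjoint(y: KSpace5D, coils: CoilSet) -> ImageSeries5D:
    """E^H y: per frame, sum_c conj(S_c) * F^-1(mask * y_{i,j,c})."""
    if y.grid != coils.grid:
        raise ValueError(f"k-space grid {y.grid} != coil grid {coils.grid}")
    masked = y.data * y.masks[:, :, None]
    img = scipy.fft.ifftn(masked, axes=_SPATIAL_AXES, norm="ortho")
    out = np.sum(np.conj(coils.maps) * img, axis=2)
    return ImageSeries5D._unchecked(out)


def ttv_forward(m: ImageSeries5D, weights: tuple[float, float] = (1.0, 1.0)) -> TTVDiffs:
    """Phi m: weighted non-circular differences along cardiac and respiratory axes."""
    if m.nc < 2:
        raise ValueError(f"temporal TV needs Nc >= 2 cardiac phases, got {m.nc}")
    wc, wr = weights
    cardiac = wc * np.diff(m.data, axis=1)
    respiratory = wr * np.diff(m.data, axis=0)
    return TTVDiffs(cardiac=cardiac, respiratory=respiratory)


def ttv_adjoint(p: TTVDiffs, weights: tuple[float, float] = (1.0, 1.0)) -> ImageSeries5D:
    """Phi^H p: negative divergence of the difference fields.

    Frame (i, j) receives ``p_c[i, j-1] - p_c[i, j] + p_r[i-1, j] - p_r[i, j]``
    with out-of-range terms zero.
    """
    wc, wr = weights
    nr = p.cardiac.shape[0]
    nc = p.cardiac.shape[1] + 1
    grid = p.cardiac.shape[2:]
    if p.respiratory.size and p.respiratory.shape != (nr - 1, nc, *grid):
        raise ValueError(
            f"respiratory diffs shape {p.respiratory.shape} inconsistent with "
            f"cardiac diffs shape {p.cardiac.shape}"
        )
    out = np.zeros((nr, nc, *grid), dtype=np.complex128)
    out[:, :-1] -= wc * p.cardiac
    out[:, 1:] += wc * p.cardiac
    if p.respiratory.size:
        out[:-1] -= wr * p.respiratory
        out[1:] += wr * p.respiratory
    return ImageSeries5D(data=out)


def phi_norm_sq_bound(weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Upper bound on ||Phi||^2: each 1D difference operator has norm^2 <= 4."""
    wc, wr = weights
    return 4.0 * (wc * wc + wr * wr)


def huber_value(u: np.ndarray, params: HuberParams) -> float:
    """Sum of the Huber function over all entries of a complex array.

    h_mu(z) = |z|^2 / (2 mu) for |z| <= mu, |z| - mu/2 otherwise; the smooth
    lower approximation to |z| with h_mu(z) <= |z| and h_mu -> |.| as mu -> 0.
    """
    mu = params.mu
    a = np.abs(u)
    quad = a * a / (2.0 * mu)
    lin = a - mu / 2.0
    return float(np.sum(np.where(a <= mu, quad, lin)))


def huber_grad(u: np.ndarray, params: HuberParams) -> np.ndarray:
    """Elementwise gradient of the Huber function: z/mu inside, z/|z| outside.

    Magnitudes never exceed 1 (the subgradient of |.| is a unit ball).
    """
    mu = params.mu
    a = np.abs(u)
    scale = 1.0 / np.maximum(a, mu)
    return u * scale


def _huber_ttv(diffs: TTVDiffs, params: HuberParams) -> float:
    v = huber_value(diffs.cardiac, params)
    if diffs.respiratory.size:
        v += huber_value(diffs.respiratory, params)
    return v


def objective(
    m: ImageSeries5D,
    y: KSpace5D,
    coils: CoilSet,
    lambda_reg: float,
    params: HuberParams,
    ttv_weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """f(m) = 1/2 ||E m - y||^2 + lambda f_mu(Phi m), over sampled entries."""
    if lambda_reg < 0:
        raise ValueError(f"lambda_reg must be nonnegative, got {lambda_reg}")
    em = apply_encoding(m, coils, y.masks)
    resid = em.data - y.data
    fid = 0.5 * float(np.vdot(resid, resid).real)
    if lambda_reg == 0:
        return fid
    return fid + lambda_reg * _huber_ttv(ttv_forward(m, ttv_weights), params)


def gradient(
    m: ImageSeries5D,
    y: KSpace5D,
    coils: CoilSet,
    lambda_reg: float,
    params: HuberParams,
    ttv_weights: tuple[float, float] = (1.0, 1.0),
) -> ImageSeries5D:
    """grad f(m) = E^H (E m - y) + lambda Phi^H f_mu'(Phi m)."""
    _, g = objective_and_gradient(m, y, coils, lambda_reg, params, ttv_weights)
    return g


def objective_and_gradient(
    m: ImageSeries5D,
    y: KSpace5D,
    coils: CoilSet,
    lambda_reg: float,
    params: HuberParams,
    ttv_weights: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, ImageSeries5D]:
    """Fused evaluation sharing the residual and the difference fields."""
    if lambda_reg < 0:
        raise ValueError(f"lambda_reg must be nonnegative, got {lambda_reg}")
    em = apply_encoding(m, coils, y.masks)
    resid = em.data - y.data
    fid = 0.5 * float(np.vdot(resid, resid).real)
    g = apply_encoding_adjoint(KSpace5D._unchecked(resid, y.masks), coils).data
    f = fid
    if lambda_reg > 0:
        diffs = ttv_forward(m, ttv_weights)
        f += lambda_reg * _huber_ttv(diffs, params)
        lam = ttv_adjoint(
            TTVDiffs(
                cardiac=huber_grad(diffs.cardiac, params),
                respiratory=huber_grad(diffs.respiratory, params)
                if diffs.respiratory.size
                else diffs.respiratory,
            ),
            ttv_weights,
        )
        g = g + lambda_reg * lam.data
    return f, ImageSeries5D._unchecked(g)
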