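"""Standalone background-field estimators.

Four filters, each mapping (field, mask) to an estimated background field:

* ``gaussian_background`` -- mask-aware (normalized) Gaussian smoothing; the
  classic homodyne high-pass applied with kernel weights renormalized over
  in-mask voxels to avoid edge leakage.
* ``polf`` -- 1st-order polynomial fit (constant + linear gradients).
* ``sphinx_filter`` -- projection onto the masked-domain orthonormalized
  solid-harmonic basis (see :mod:`mubafire.ssh_basis`).
* ``dipf`` -- projection onto dipole fields: an exterior pseudo-susceptibility
  is fitted by conjugate gradients so that its dipole-convolved field best
  explains the measured field inside the mask (Tikhonov regularized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .core import (
    DegenerateFitError,
    FieldMap,
    InvalidInputError,
    Mask,
    SusceptibilityMap,
    VoxelGrid,
    hz_per_ppm,
)
from . import ssh_basis


# ---------------------------------------------------------------------------
# Gaussian


def gaussian_background(fieldmap: FieldMap, mask: Mask, sigma: float) -> FieldMap:
    """Mask-limited Gaussian estimate of the background field.

    At each masked voxel the background is the Gaussian-weighted mean of the
    field over in-mask voxels within a kernel truncated at 3*sigma (sigma in
    voxels); weights of out-of-mask voxels are excluded and the remaining
    weights renormalized.
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    mask.require_nonempty()
    radius = int(math.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    w1 = np.exp(-(x * x) / (2.0 * sigma * sigma))

    m = mask.values.astype(float)
    num = fieldmap.values * m
    den = m
    for axis in range(3):
        num = ndimage.correlate1d(num, w1, axis=axis, mode="constant", cval=0.0)
        den = ndimage.correlate1d(den, w1, axis=axis, mode="constant", cval=0.0)
    bg = np.zeros(fieldmap.grid.shape)
    inside = mask.values & (den > 0)
    bg[inside] = num[inside] / den[inside]
    return FieldMap(fieldmap.grid, bg)


# ---------------------------------------------------------------------------
# 1st-order polynomial


def polf(fieldmap: FieldMap, mask: Mask) -> tuple[np.ndarray, FieldMap]:
    """Least-squares fit of ``a + b*x + c*y + d*z`` over masked voxels.

    Coordinates are physical (mm, voxel index times voxel size, origin at
    voxel [0,0,0]).  Returns the four coefficients and the fitted plane
    evaluated inside the mask.  Only the 1st order is supported: higher
    polynomial orders do not correspond to any physical solution of the
    static-field problem.
    """
    mask.require_nonempty()
    idx = np.argwhere(mask.values)
    if idx.shape[0] < 4:
        raise DegenerateFitError("mask spans fewer than 4 voxels")
    coords = idx * np.asarray(fieldmap.grid.voxel_size)
    # center and scale internally for conditioning; map back afterwards
    mu = coords.mean(axis=0)
    sc = coords.std(axis=0)
    sc[sc == 0] = 1.0
    A = np.column_stack([np.ones(len(coords))] + [(coords[:, i] - mu[i]) / sc[i] for i in range(3)])
    b = fieldmap.values[mask.values]
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("coplanar mask: 1st-order fit is rank deficient")
    grad = sol[1:] / sc
    coeffs = np.concatenate([[sol[0] - grad @ mu], grad])
    bg = np.zeros(fieldmap.grid.shape)
    bg[mask.values] = A @ sol
    return coeffs, FieldMap(fieldmap.grid, bg)


# ---------------------------------------------------------------------------
# SPHINX


def sphinx_filter(
    fieldmap: FieldMap, mask: Mask, order: int, cache: bool = True
) -> tuple[FieldMap, ssh_basis.SSHCoefficients]:
    """Solid-harmonic background estimate at the given expansion order."""
    if order < 1:
        raise InvalidInputError("order must be >= 1")
    basis = ssh_basis.get_basis(mask, order, cache=cache)
    coeffs, background = ssh_basis.project(fieldmap, basis)
    return background, coeffs


# ---------------------------------------------------------------------------
# dipole kernel and forward model


@dataclass
class DipoleKernel:
    """Spectral unit dipole response on a (padded) grid.

    ``spectrum`` holds ``D(k) = 1/3 - (k . b0)^2 / |k|^2`` sampled on the
    rfft frequency grid, with D(0) = 0 (the mean field is undetermined by
    susceptibility differences).
    """

    grid: VoxelGrid
    spectrum: np.ndarray


def dipole_kernel(grid: VoxelGrid) -> DipoleKernel:
    """Fourier-domain dipole kernel for the grid's b0 direction."""
    freqs = [
        sfft.fftfreq(n, d=v) for n, v in zip(grid.shape[:2], grid.voxel_size[:2])
    ] + [sfft.rfftfreq(grid.shape[2], d=grid.voxel_size[2])]
    KX, KY, KZ = np.meshgrid(*freqs, indexing="ij", sparse=True)
    e = grid.b0_direction
    kpar = KX * e[0] + KY * e[1] + KZ * e[2]
    k2 = KX * KX + KY * KY + KZ * KZ
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 / 3.0 - np.where(k2 > 0, kpar * kpar / np.where(k2 > 0, k2, 1.0), 0.0)
    D[(0,) * D.ndim] = 0.0
    return DipoleKernel(grid, D)


def pad_widths(shape: tuple[int, int, int], pad_fraction: float) -> list[int]:
    return [int(math.ceil(pad_fraction * n)) for n in shape]


def forward_field_ppm(
    chi_ppm: np.ndarray, grid: VoxelGrid, pad_fraction: float = 1.0 / 8.0
) -> np.ndarray:
    """Dipole-convolve a susceptibility volume (ppm): returns ``d * chi``
    in ppm of relative field shift, computed spectrally with zero padding."""
    pads = pad_widths(grid.shape, pad_fraction)
    padded = np.pad(chi_ppm, [(p, p) for p in pads])
    pgrid = VoxelGrid(padded.shape, grid.voxel_size, grid.b0_direction, grid.b_base)
    D = dipole_kernel(pgrid).spectrum
    out = sfft.irfftn(D * sfft.rfftn(padded), s=padded.shape)
    sl = tuple(slice(p, p + n) for p, n in zip(pads, grid.shape))
    return out[sl]


def forward_field_hz(
    chi: SusceptibilityMap, pad_fraction: float = 1.0 / 8.0
) -> FieldMap:
    """Field in Hz induced by a susceptibility map at the grid's B_base."""
    rel = forward_field_ppm(chi.values, chi.grid, pad_fraction)
    return FieldMap(chi.grid, rel * hz_per_ppm(chi.grid.b_base))


# ---------------------------------------------------------------------------
# DIPF


@dataclass
class DipfConfig:
    """Dipole-filter parameters.

    lambda_tik : Tikhonov weight on the exterior pseudo-susceptibility
        amplitude, in the Hz-field / ppm-susceptibility convention used
        throughout this package.  The penalty is what keeps the exterior fit
        from mimicking fields of truly distant sources with large-amplitude
        near-surface dipole layers.
    n_iter : fixed conjugate-gradient iteration count (no stopping tolerance).
    pad_fraction : zero padding per side as a fraction of the matrix size.
    allow_pad_sources : whether pseudo-susceptibility may occupy the
        zero-padded margin in addition to the measured-but-unmasked region.
    hard_support : enforce chi_ext = 0 inside the mask by hard support
        restriction (projection each step).  When False, the mask interior is
        instead penalized softly through the Tikhonov term.
    """

    lambda_tik: float = 500.0
    n_iter: int = 50
    pad_fraction: float = 1.0 / 8.0
    allow_pad_sources: bool = True
    hard_support: bool = True

    def __post_init__(self) -> None:
        if self.lambda_tik < 0:
            raise InvalidInputError("lambda_tik must be >= 0")
        if self.n_iter < 1:
            raise InvalidInputError("n_iter must be >= 1")
        if self.pad_fraction < 0:
            raise InvalidInputError("pad_fraction must be >= 0")


@dataclass
class DipfResult:
    chi_ext: SusceptibilityMap
    background: FieldMap
    residual_history: np.ndarray
    config: DipfConfig = dc_field(default_factory=DipfConfig)


def dipf(
    fieldmap: FieldMap,
    mask: Mask,
    config: DipfConfig | None = None,
    support: Mask | None = None,
    fit_mask: Mask | None = None,
    record_iters: list[int] | None = None,
) -> DipfResult:
    """Projection onto dipole fields by conjugate gradients.

    Minimizes ``|| M (b - C d * chi) ||^2 + lambda ||chi||^2`` over a
    pseudo-susceptibility ``chi`` supported outside the volume of interest
    (C converts ppm to Hz at B_base).  The normal equations are solved by CG
    with a fixed iteration count, starting from chi = 0, with the support
    restriction applied every step.

    Parameters
    ----------
    support : optional
        Solution support on the unpadded grid; default is the mask exterior
        (plus the padded margin when ``allow_pad_sources``).
    fit_mask : optional
        Domain on which the data term is evaluated; defaults to ``mask``.
    record_iters : optional
        Iteration counts at which to snapshot the background field; the
        snapshots are returned as an extra attribute ``snapshots``.
    """
    config = config or DipfConfig()
    mask.require_nonempty()
    b = fieldmap.values
    if not np.all(np.isfinite(b[mask.values])):
        raise InvalidInputError("NaN/Inf in masked field")
    grid = fieldmap.grid
    pads = pad_widths(grid.shape, config.pad_fraction)
    pad_spec = [(p, p) for p in pads]
    sl = tuple(slice(p, p + n) for p, n in zip(pads, grid.shape))

    fitm = (fit_mask or mask).values
    M = np.pad(fitm, pad_spec)
    if support is not None:
        S = np.pad(support.values, pad_spec)
    else:
        S = ~np.pad(mask.values, pad_spec, constant_values=not config.allow_pad_sources)
        if not config.allow_pad_sources:
            inside = np.zeros_like(S)
            inside[sl] = True
            S &= inside
    if config.hard_support and not S.any():
        raise InvalidInputError("empty pseudo-susceptibility support")

    pshape = M.shape
    pgrid = VoxelGrid(pshape, grid.voxel_size, grid.b0_direction, grid.b_base)
    D = dipole_kernel(pgrid).spectrum
    # fields in Hz, pseudo-susceptibility in ppm: lambda penalizes ppm-scale
    # amplitudes, which limits how much large-amplitude near-surface dipole
    # layers can mimic fields of truly distant sources
    C = hz_per_ppm(grid.b_base)

    def fwd(v: np.ndarray) -> np.ndarray:
        return C * sfft.irfftn(D * sfft.rfftn(v), s=pshape)

    def proj(v: np.ndarray) -> np.ndarray:
        if config.hard_support:
            return np.where(S, v, 0.0)
        return v

    b_pad = np.pad(np.where(fitm, b, 0.0), pad_spec)
    Mb = np.where(M, b_pad, 0.0)
    lam = config.lambda_tik
    # Tikhonov weight: unit weight on the (exterior) support in hard mode,
    # the literal mask-interior weight W_T = m in soft mode
    Wt = 1.0 if config.hard_support else np.pad(mask.values, pad_spec).astype(float)

    # CG on the normal equations (A^T A + lam I) x = A^T b, A = M F P_S.
    x = np.zeros(pshape)
    Fx_fit = np.zeros(pshape)  # M F x, tracked incrementally for the history
    r = proj(fwd(Mb))
    p = r.copy()
    rs = float((r * r).sum())
    history = []
    snapshots: dict[int, FieldMap] = {}
    want = set(record_iters or [])
    for it in range(1, config.n_iter + 1):
        Fp_fit = np.where(M, fwd(proj(p)), 0.0)
        Hp = proj(fwd(Fp_fit)) + lam * (Wt * p)
        pHp = float((p * Hp).sum())
        if pHp <= 0 or rs == 0.0:
            history.append(history[-1] if history else float(np.linalg.norm(Mb)))
            if it in want:
                snapshots[it] = FieldMap(grid, fwd(proj(x))[sl])
            continue
        alpha = rs / pHp
        x += alpha * p
        Fx_fit += alpha * Fp_fit
        r -= alpha * Hp
        rs_new = float((r * r).sum())
        p = r + (rs_new / rs) * p
        rs = rs_new
        history.append(float(np.linalg.norm(Mb - Fx_fit)))
        if it in want:
            snapshots[it] = FieldMap(grid, fwd(proj(x))[sl])

    x = proj(x)
    background = fwd(x)[sl]
    chi_ext = SusceptibilityMap(grid, x[sl])
    result = DipfResult(chi_ext, FieldMap(grid, background), np.asarray(history), config)
    if record_iters:
        result.snapshots = snapshots  # type: ignore[attr-defined]
    return result
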