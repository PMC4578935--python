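"""Voxel-grid data model, unit conventions and field-map construction.

All field maps are carried in Hz (off-resonance frequency); magnetic
susceptibility is carried in ppm.  The conversion between the two is

    df [Hz] = GAMMA_BAR_HZ_PER_T * B_base [T] * chi [ppm] * 1e-6

with the proton gyromagnetic ratio ``gamma / 2 pi``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Proton gyromagnetic ratio over 2*pi, Hz per tesla.
GAMMA_BAR_HZ_PER_T = 42.577478518e6


def hz_per_ppm(b_base: float) -> float:
    """Field shift in Hz produced by a 1 ppm susceptibility-induced
    relative field change at main field strength ``b_base`` (tesla)."""
    return GAMMA_BAR_HZ_PER_T * b_base * 1e-6


class InvalidInputError(ValueError):
    """Raised when an operation receives inputs outside its contract."""


class DegenerateBasisError(RuntimeError):
    """Raised when a basis vector vanishes during orthonormalization."""


class DegenerateFitError(RuntimeError):
    """Raised when a least-squares fit domain is rank deficient."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid with acquisition geometry.

    Parameters
    ----------
    shape : tuple of int
        Matrix size (nx, ny, nz).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    b0_direction : tuple of float
        Unit vector of the main magnetic field (default along z).
    b_base : float
        Main field strength in tesla.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    b_base: float = 9.4

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise InvalidInputError(f"invalid grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidInputError(f"voxel sizes must be > 0: {self.voxel_size}")
        norm = float(np.linalg.norm(self.b0_direction))
        if abs(norm - 1.0) > 1e-12:
            raise InvalidInputError("b0_direction must be a unit vector")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "b0_direction", tuple(float(v) for v in self.b0_direction))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coords_mm(self, origin: np.ndarray | None = None):
        """Physical coordinate volumes (X, Y, Z) in mm.

        Coordinates are voxel index times voxel size; ``origin`` (mm) is
        subtracted when given.  Only relative coordinates enter any of the
        downstream math, so no half-voxel shift is applied.
        """
        axes = [np.arange(n, dtype=float) * v for n, v in zip(self.shape, self.voxel_size)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        if origin is not None:
            X = X - origin[0]
            Y = Y - origin[1]
            Z = Z - origin[2]
        return X, Y, Z

    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])


def _check_volume(grid: VoxelGrid, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if tuple(values.shape) != grid.shape:
        raise InvalidInputError(
            f"{what} shape {values.shape} does not match grid {grid.shape}"
        )
    return values


@dataclass
class FieldMap:
    """Scalar 3D field-offset volume in Hz."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_volume(self.grid, self.values, "field").astype(float)

    def masked(self, mask: "Mask") -> np.ndarray:
        return self.values[mask.values]


@dataclass
class Mask:
    """Boolean volume-of-interest on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_volume(self.grid, self.values, "mask").astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> None:
        if not self.values.any():
            raise InvalidInputError("mask contains no voxels")

    def center_of_mass_mm(self) -> np.ndarray:
        idx = np.argwhere(self.values)
        return idx.mean(axis=0) * np.asarray(self.grid.voxel_size)


@dataclass
class SusceptibilityMap:
    """Scalar 3D susceptibility volume in ppm."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_volume(self.grid, self.values, "susceptibility").astype(float)


@dataclass
class EchoSeries:
    """Unwrapped phase volumes over one or more echo times.

    ``phases`` has shape ``grid.shape + (n_echoes,)`` in radians;
    ``echo_times`` are in seconds and strictly increasing.
    """

    grid: VoxelGrid
    echo_times: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.echo_times = np.atleast_1d(np.asarray(self.echo_times, dtype=float))
        self.phases = np.asarray(self.phases, dtype=float)
        if self.echo_times.size < 1:
            raise InvalidInputError("at least one echo is required")
        if np.any(np.diff(self.echo_times) <= 0):
            raise InvalidInputError("echo times must be strictly increasing")
        expected = self.grid.shape + (self.echo_times.size,)
        if tuple(self.phases.shape) != expected:
            raise InvalidInputError(
                f"phases shape {self.phases.shape}, expected {expected}"
            )


@dataclass
class FieldSummary:
    """Masked summary statistics of a field map."""

    mean: float
    std: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_voxels: int

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        ).to_csv(path, index=False)

    def header_json(self) -> str:
        return json.dumps(
            {"mean": self.mean, "std": self.std, "n_voxels": self.n_voxels}
        )


def field_from_phase(echoes: EchoSeries, mask: Mask) -> FieldMap:
    """Field map in Hz from unwrapped phase by linear regression over echoes.

    The per-voxel field is the least-squares slope of phase versus echo time
    divided by 2*pi; with a single echo it reduces to phi / (2*pi*TE).
    Voxels outside the mask are set to 0.
    """
    mask.require_nonempty()
    t = echoes.echo_times
    phi = echoes.phases
    if t.size == 1:
        b = phi[..., 0] / (2.0 * np.pi * t[0])
    else:
        tc = t - t.mean()
        # unweighted OLS slope; the intercept (phase offset) is discarded
        slope = np.tensordot(phi - phi.mean(axis=-1, keepdims=True), tc, axes=([-1], [0]))
        slope /= np.dot(tc, tc)
        b = slope / (2.0 * np.pi)
    out = np.where(mask.values, b, 0.0)
    if not np.all(np.isfinite(out[mask.values])):
        raise InvalidInputError("non-finite field values inside mask")
    return FieldMap(echoes.grid, out)


def masked_summary(fieldmap: FieldMap, mask: Mask, n_bins: int = 64) -> FieldSummary:
    """Mean, population std (divisor n) and histogram over masked voxels."""
    mask.require_nonempty()
    vals = fieldmap.masked(mask)
    counts, edges = np.histogram(vals, bins=n_bins)
    return FieldSummary(
        mean=float(vals.mean()),
        std=float(vals.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
        n_voxels=vals.size,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(path: str | Path, grid: VoxelGrid, values: np.ndarray) -> None:
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, grid.affine()), str(path))


def save_field(path: str | Path, fieldmap: FieldMap) -> None:
    save_volume(path, fieldmap.grid, fieldmap.values)


def save_mask(path: str | Path, mask: Mask) -> None:
    save_volume(path, mask.grid, mask.values)


def _grid_from_img(img, **grid_kwargs) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(shape=tuple(img.shape[:3]), voxel_size=zooms, **grid_kwargs)


def load_field(path: str | Path, **grid_kwargs) -> FieldMap:
    img = nib.load(str(path))
    grid = _grid_from_img(img, **grid_kwargs)
    return FieldMap(grid, np.asarray(img.dataobj, dtype=float))


def load_mask(path: str | Path, **grid_kwargs) -> Mask:
    img = nib.load(str(path))
    grid = _grid_from_img(img, **grid_kwargs)
    return Mask(grid, np.asarray(img.dataobj) > 0)
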