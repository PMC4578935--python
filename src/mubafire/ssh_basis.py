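"""Real regular solid spherical harmonics orthonormalized on a masked domain.

Background fields are source-free inside the volume of interest and hence
harmonic; regular solid harmonics ``v_lm = N_lm * r^l * Y_lm`` span exactly
those fields.  On a finite, non-spherical voxel domain (a brain mask) the
continuum orthogonality of the ``v_lm`` is lost, so the discrete basis is
re-orthonormalized with a Gram-Schmidt procedure under the masked voxelwise
inner product ``<a|b> = sum_{r in mask} a(r) b(r)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .core import (
    DegenerateBasisError,
    FieldMap,
    InvalidInputError,
    Mask,
    VoxelGrid,
)

#: hard ceiling on the expansion order (basis size grows as (n+1)^2)
ORDER_MAX_LIMIT = 15


@dataclass(frozen=True)
class SolidHarmonicSpec:
    """Expansion order, physical center (mm) and radius normalization (mm)."""

    order_max: int
    center: tuple[float, float, float]
    radius_scale: float

    def __post_init__(self) -> None:
        if not (0 <= self.order_max <= ORDER_MAX_LIMIT):
            raise InvalidInputError(
                f"order_max must be in [0, {ORDER_MAX_LIMIT}], got {self.order_max}"
            )
        if self.radius_scale <= 0:
            raise InvalidInputError("radius_scale must be > 0")

    @property
    def n_vectors(self) -> int:
        return (self.order_max + 1) ** 2


def lm_order(order_max: int) -> list[tuple[int, int]]:
    """(l, m) pairs in basis order: l ascending, m from -l to l."""
    return [(l, m) for l in range(order_max + 1) for m in range(-l, l + 1)]


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonic (Condon-Shortley-free).

    ``theta`` is the polar angle from the b0 axis, ``phi`` the azimuth.
    """
    if abs(m) > l:
        raise InvalidInputError(f"|m| <= l required, got l={l}, m={m}")
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real
    y = sph_harm_y(l, abs(m), theta, phi)
    # (-1)^m cancels the Condon-Shortley phase of scipy's Y_lm
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    return np.sqrt(2.0) * (-1.0) ** m * y.imag


def solid_harmonic(
    l: int,
    m: int,
    grid: VoxelGrid,
    center: tuple[float, float, float],
    radius_scale: float,
) -> np.ndarray:
    """Evaluate ``(r / radius_scale)^l * Y_lm(theta, phi)`` at voxel centers.

    The radial normalization keeps high orders conditioned (r <= 1 when
    ``radius_scale`` bounds the domain).  The value at r = 0 is 0 for l >= 1.
    """
    if abs(m) > l or l < 0:
        raise InvalidInputError(f"invalid degree/order l={l}, m={m}")
    X, Y, Z = grid.coords_mm(origin=np.asarray(center, dtype=float))
    r = np.sqrt(X * X + Y * Y + Z * Z)
    cosab = np.divide(Z, r, out=np.zeros_like(Z), where=r > 0)
    theta = np.arccos(np.clip(cosab, -1.0, 1.0))
    theta = np.where(r > 0, theta, 0.0)
    phi = np.arctan2(Y, X)
    v = (r / radius_scale) ** l * real_sph_harm(l, m, theta, phi)
    if l >= 1:
        v = np.where(r > 0, v, 0.0)
    return v


def raw_basis(spec: SolidHarmonicSpec, grid: VoxelGrid) -> np.ndarray:
    """All solid harmonics up to order_max, stacked as (..., n_vectors)."""
    vols = [
        solid_harmonic(l, m, grid, spec.center, spec.radius_scale)
        for l, m in lm_order(spec.order_max)
    ]
    return np.stack(vols, axis=-1)


def default_spec(mask: Mask, order_max: int) -> SolidHarmonicSpec:
    """Center the basis on the mask center of mass; scale r by the maximum
    masked-voxel distance from that center (so r^l stays in [0, 1])."""
    mask.require_nonempty()
    center = mask.center_of_mass_mm()
    idx = np.argwhere(mask.values) * np.asarray(mask.grid.voxel_size)
    radius = float(np.linalg.norm(idx - center, axis=1).max())
    return SolidHarmonicSpec(order_max, tuple(center), max(radius, 1e-6))


@dataclass
class SSHBasis:
    """Masked-domain orthonormal solid-harmonic basis.

    ``matrix`` holds the basis column vectors sampled at the masked voxels
    (shape n_masked x n_vectors); full volumes are reconstructed on demand.
    """

    spec: SolidHarmonicSpec
    mask: Mask
    matrix: np.ndarray
    gram_residual: float

    @property
    def n_vectors(self) -> int:
        return self.matrix.shape[1]

    def volume(self, i: int) -> np.ndarray:
        out = np.zeros(self.mask.grid.shape)
        out[self.mask.values] = self.matrix[:, i]
        return out

    @property
    def vectors(self) -> list[np.ndarray]:
        return [self.volume(i) for i in range(self.n_vectors)]

    def truncated(self, order_max: int) -> "SSHBasis":
        """Restrict to orders <= order_max.

        Gram-Schmidt is sequential, so the leading (order_max+1)^2 columns
        of a higher-order basis are exactly the lower-order basis.
        """
        if order_max > self.spec.order_max:
            raise InvalidInputError("cannot truncate to a higher order")
        k = (order_max + 1) ** 2
        sub = self.matrix[:, :k]
        gram = sub.T @ sub
        resid = float(np.abs(gram - np.eye(k)).max())
        spec = SolidHarmonicSpec(order_max, self.spec.center, self.spec.radius_scale)
        return SSHBasis(spec, self.mask, sub, resid)


@dataclass
class SSHCoefficients:
    """Projection coefficients c_lm (Hz), ordered like the basis."""

    values: np.ndarray
    order_max: int

    def lm(self) -> list[tuple[int, int]]:
        return lm_order(self.order_max)


def orthonormalize(
    raw: np.ndarray,
    mask: Mask,
    spec: SolidHarmonicSpec | None = None,
) -> SSHBasis:
    """Gram-Schmidt orthonormalization of raw volumes on the masked domain.

    Each vector has the projections onto all previously accepted vectors
    subtracted (classical update applied twice, i.e. one re-orthogonalization
    pass, which is required to hold the Gram residual below 1e-8 at order 10
    in floating point) and is then normalized.

    Parameters
    ----------
    raw : ndarray
        Either a stacked volume array (*grid.shape, k) or (n_masked, k).
    """
    mask.require_nonempty()
    if raw.ndim == 4:
        V = raw[mask.values, :].astype(float).copy()
    elif raw.ndim == 2:
        V = raw.astype(float).copy()
    else:
        raise InvalidInputError("raw basis must be a 4D stack or 2D matrix")
    n_masked, k = V.shape
    if spec is None:
        order = int(round(np.sqrt(k))) - 1
        spec = default_spec(mask, order) if (order + 1) ** 2 == k else None
    pairs = lm_order(int(np.sqrt(k)) - 1) if int(np.sqrt(k)) ** 2 == k else None

    Q = np.empty_like(V)
    for j in range(k):
        v = V[:, j]
        pre_norm = np.linalg.norm(v)
        if j > 0:
            Qj = Q[:, :j]
            for _ in range(2):  # CGS with one re-orthogonalization pass
                v = v - Qj @ (Qj.T @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10 * max(pre_norm, 1e-300) or norm == 0.0:
            name = f"(l, m) = {pairs[j]}" if pairs else f"index {j}"
            raise DegenerateBasisError(
                f"basis vector {name} is linearly dependent on the masked domain"
            )
        Q[:, j] = v / norm

    gram = Q.T @ Q
    resid = float(np.abs(gram - np.eye(k)).max())
    if spec is None:
        spec = SolidHarmonicSpec(ORDER_MAX_LIMIT, (0.0, 0.0, 0.0), 1.0)
    return SSHBasis(spec, mask, Q, resid)


def build_basis(mask: Mask, order_max: int, spec: SolidHarmonicSpec | None = None) -> SSHBasis:
    """Raw solid harmonics on the grid + masked orthonormalization."""
    if spec is None:
        spec = default_spec(mask, order_max)
    raw = raw_basis(spec, mask.grid)
    return orthonormalize(raw, mask, spec=spec)


def project(fieldmap: FieldMap, basis: SSHBasis) -> tuple[SSHCoefficients, FieldMap]:
    """Project a field onto the basis: ``c_lm = <b|u_lm>`` over masked voxels.

    Returns the coefficients and the background field ``sum c_lm u_lm``
    (zero outside the mask).
    """
    if fieldmap.grid.shape != basis.mask.grid.shape:
        raise InvalidInputError("field and basis grids differ")
    b = fieldmap.values[basis.mask.values]
    c = basis.matrix.T @ b
    bg = np.zeros(fieldmap.grid.shape)
    bg[basis.mask.values] = basis.matrix @ c
    return SSHCoefficients(c, basis.spec.order_max), FieldMap(fieldmap.grid, bg)


# ---------------------------------------------------------------------------
# basis cache: orthonormalization at order 10 on a large mask is the single
# most expensive repeated step, and the chain re-uses the same mask.

_CACHE: dict[str, SSHBasis] = {}


def _mask_key(mask: Mask) -> str:
    h = hashlib.sha1(np.packbits(mask.values).tobytes())
    h.update(repr(mask.grid).encode())
    return h.hexdigest()


def get_basis(mask: Mask, order_max: int, cache: bool = True) -> SSHBasis:
    """Basis for (mask, order); cached and truncated from higher orders."""
    if not cache:
        return build_basis(mask, order_max)
    key = _mask_key(mask)
    hit = _CACHE.get(key)
    if hit is not None and hit.spec.order_max >= order_max:
        return hit if hit.spec.order_max == order_max else hit.truncated(order_max)
    basis = build_basis(mask, order_max)
    _CACHE[key] = basis
    if len(_CACHE) > 8:  # keep memory bounded across many simulation samples
        _CACHE.pop(next(iter(_CACHE)))
    return basis


def clear_cache() -> None:
    _CACHE.clear()


# ---------------------------------------------------------------------------
# serialization: a 4D NIfTI stack of basis volumes + JSON metadata


def save_basis(path, basis: SSHBasis) -> None:
    """Write the basis as a 4D NIfTI volume plus a JSON sidecar
    (order, center, radius_scale, gram_residual)."""
    import json
    from pathlib import Path

    import nibabel as nib

    path = Path(path)
    stack = np.zeros(basis.mask.grid.shape + (basis.n_vectors,))
    stack[basis.mask.values, :] = basis.matrix
    nib.save(nib.Nifti1Image(stack, basis.mask.grid.affine()), str(path))
    meta = {
        "order_max": basis.spec.order_max,
        "center": list(basis.spec.center),
        "radius_scale": basis.spec.radius_scale,
        "gram_residual": basis.gram_residual,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_basis(path, mask: Mask) -> SSHBasis:
    """Read a basis written by :func:`save_basis`; the mask must match the
    one the basis was built on."""
    import json
    from pathlib import Path

    import nibabel as nib

    path = Path(path)
    stack = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if stack.shape[:3] != mask.grid.shape:
        raise InvalidInputError("basis volume shape does not match mask grid")
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    spec = SolidHarmonicSpec(
        meta["order_max"], tuple(meta["center"]), meta["radius_scale"]
    )
    return SSHBasis(spec, mask, stack[mask.values, :], meta["gram_residual"])
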