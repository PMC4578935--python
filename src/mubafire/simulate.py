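"""Monte Carlo generator of realistic distorted field maps.

Each sample couples a brain-like susceptibility phantom with randomized
long-range harmonic field inhomogeneities and measurement noise:

    b_obs(r) = [f_base + b_inh(r)] * (d * chi)(r) * 1e-6 + b_inh(r) + noise

with f_base the main field expressed in Hz, d the unit dipole kernel and
chi = chi_stat + chi_var in ppm.  The reference (ground-truth internal)
field b_ref is obtained by re-running the dipole convolution with the
exterior susceptibility replaced by the mask-mean internal value — so only
sources of contrast *inside* the volume of interest contribute — and
removing the masked mean.

The anatomy is a parametric phantom (perturbed ellipsoid, tube-shaped
vessels, ventricle blobs, exterior air-like cavities); its susceptibility
values follow the tissue conventions used throughout: tissue -9 +/- 0.2 ppm,
vessels -7.9 ppm, ventricles -9 ppm, exterior -6 ppm, cavities positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .core import (
    FieldMap,
    GAMMA_BAR_HZ_PER_T,
    InvalidInputError,
    Mask,
    SusceptibilityMap,
    VoxelGrid,
)
from . import ssh_basis
from .filters import forward_field_ppm

#: matrix presets: the study matrix and a reduced desk-scale variant
PRESETS = {
    "paper-full": (138, 162, 106),
    "desk-small": (72, 80, 56),
}

LABEL_EXTERIOR, LABEL_TISSUE, LABEL_VESSEL, LABEL_VENTRICLE, LABEL_CAVITY = range(5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and susceptibility values of the synthetic brain phantom.

    Structure sizes are specified as fractions of the matrix so presets at
    different resolutions produce geometrically similar phantoms.
    """

    matrix: tuple[int, int, int] = PRESETS["desk-small"]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b_base: float = 9.4
    chi_tissue_ppm: float = -9.0
    chi_spread_ppm: float = 0.2
    chi_vessel_ppm: float = -7.9
    chi_ventricle_ppm: float = -9.0
    chi_exterior_ppm: float = -6.0
    chi_cavity_ppm: float = 0.4
    brain_fraction: float = 0.31       # ellipsoid semi-axes as matrix fraction
    surface_perturbation: float = 0.06
    n_vessels: int = 4
    vessel_radius_fraction: float = 0.010
    n_ventricles: int = 2
    ventricle_radius_fraction: float = 0.07
    n_cavities: int = 3
    cavity_radius_fraction: float = 0.055
    margin_fraction: float = 0.08
    seed: int = 0


@dataclass(frozen=True)
class InhomogeneitySpec:
    """Randomized harmonic background field: solid-harmonic sum with random
    coefficients and polarity, rescaled so max |b_inh| = amplitude_bound."""

    order_max: int = 4
    amplitude_bound: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order_max < 1:
            raise InvalidInputError("order_max must be >= 1")


@dataclass
class SimulationSample:
    mask: Mask
    chi: SusceptibilityMap
    b_inh: FieldMap
    b_obs: FieldMap
    b_ref: FieldMap
    noise_sigma: float
    seed: int
    labels: np.ndarray | None = None


def _smooth_field(rng, shape, sigma_vox: float) -> np.ndarray:
    """Unit-amplitude smooth random field (Gaussian-filtered white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_phantom(spec: PhantomSpec) -> tuple[Mask, SusceptibilityMap, np.ndarray]:
    """Brain-like mask, static susceptibility and a structure label volume.

    Deterministic per spec.seed.  The mask is a smoothly perturbed ellipsoid
    kept strictly inside the volume by ``margin_fraction``; vessels are tube
    segments, ventricles central blobs, cavities spheres tangent to the
    outer surface.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.matrix)
    grid = VoxelGrid(shape, spec.voxel_size, b_base=spec.b_base)
    nx, ny, nz = shape
    semi = np.array([spec.brain_fraction * n for n in shape])
    center = (np.array(shape) - 1) / 2.0

    margin = np.array([spec.margin_fraction * n for n in shape])
    if np.any(semi * (1 + spec.surface_perturbation * 1.5) + margin > np.array(shape) / 2.0):
        raise InvalidInputError(
            "phantom does not fit: brain plus margin exceeds the matrix"
        )

    ii = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    u = [(ii[a] - center[a]) / semi[a] for a in range(3)]
    rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    perturb = _smooth_field(rng, shape, 0.08 * min(shape))
    mask_arr = rho <= 1.0 + spec.surface_perturbation * perturb

    labels = np.full(shape, LABEL_EXTERIOR, dtype=np.int8)
    labels[mask_arr] = LABEL_TISSUE

    # tissue texture: smooth random field within +/- chi_spread
    texture = _smooth_field(rng, shape, 0.05 * min(shape)) * spec.chi_spread_ppm
    chi = np.full(shape, spec.chi_exterior_ppm)
    chi[mask_arr] = spec.chi_tissue_ppm + texture[mask_arr]

    # ventricles: ellipsoidal blobs near the center, at the tissue average
    for _ in range(spec.n_ventricles):
        c = center + rng.uniform(-0.15, 0.15, 3) * semi
        r = spec.ventricle_radius_fraction * min(shape) * rng.uniform(0.7, 1.2)
        ax = r * rng.uniform(0.6, 1.4, 3)
        d = sum(((ii[a] - c[a]) / ax[a]) ** 2 for a in range(3))
        blob = (d <= 1.0) & mask_arr
        chi[blob] = spec.chi_ventricle_ppm
        labels[blob] = LABEL_VENTRICLE

    # vessels: straight tube segments well inside the brain
    X = np.stack(ii, axis=-1)
    for _ in range(spec.n_vessels):
        p0 = center + rng.uniform(-0.5, 0.5, 3) * semi
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        half_len = 0.45 * semi.min()
        rad = spec.vessel_radius_fraction * min(shape)
        lo = np.maximum(np.floor(p0 - half_len - 3 * rad).astype(int), 0)
        hi = np.minimum(np.ceil(p0 + half_len + 3 * rad).astype(int) + 1, shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        P = X[sl] - p0
        t = np.clip(P @ d, -half_len, half_len)
        dist = np.linalg.norm(P - t[..., None] * d, axis=-1)
        tube = dist <= rad
        sub_mask = mask_arr[sl]
        chi[sl][tube & sub_mask] = spec.chi_vessel_ppm
        labels[sl][tube & sub_mask] = LABEL_VESSEL

    # exterior cavities: positive-susceptibility pockets hugging the surface
    for _ in range(spec.n_cavities):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        r = spec.cavity_radius_fraction * min(shape) * rng.uniform(0.7, 1.2)
        c = center + d * (semi * 1.04) + d * r
        dist = np.sqrt(sum((ii[a] - c[a]) ** 2 for a in range(3)))
        pocket = (dist <= r) & ~mask_arr
        chi[pocket] = spec.chi_cavity_ppm
        labels[pocket] = LABEL_CAVITY

    return Mask(grid, mask_arr), SusceptibilityMap(grid, chi), labels


def random_inhomogeneity(spec: InhomogeneitySpec, grid: VoxelGrid) -> FieldMap:
    """Random solid-harmonic background field, bounded at amplitude_bound.

    Coefficients are drawn per (l, m) with random polarity and a 1/(l+1)
    amplitude decay (low shim orders dominate real magnets); the summed
    field is rescaled so its volume maximum equals ``amplitude_bound`` Hz
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    center = (np.array(grid.shape) - 1) / 2.0 * np.asarray(grid.voxel_size)
    radius = float(np.linalg.norm(center)) or 1.0
    field = np.zeros(grid.shape)
    for l in range(spec.order_max + 1):
        for m in range(-l, l + 1):
            c = rng.standard_normal() / (l + 1.0)
            field += c * ssh_basis.solid_harmonic(l, m, grid, tuple(center), radius)
    peak = np.abs(field).max()
    if peak > 0:
        field *= spec.amplitude_bound / peak
    return FieldMap(grid, field)


def simulate_sample(
    phantom: PhantomSpec,
    inh_spec: InhomogeneitySpec | None = None,
    noise_sigma: float = 0.3,
    b_base: float | None = None,
    pad_fraction: float = 1.0 / 8.0,
) -> SimulationSample:
    """One Monte Carlo draw of (mask, chi, b_inh, b_obs, b_ref).

    chi_var adds smooth random contrast plus a few sharp-edged blobs inside
    the mask, clipped to +/- chi_spread; exterior cavities are part of the
    static phantom and are treated as exterior sources (excluded from the
    reference).  Bit-reproducible from the two spec seeds.
    """
    if b_base is not None:
        phantom = replace(phantom, b_base=b_base)
    inh_spec = inh_spec or InhomogeneitySpec(seed=phantom.seed)
    mask, chi_stat, labels = make_phantom(phantom)
    grid = mask.grid
    rng = np.random.default_rng([phantom.seed, inh_spec.seed, 0x5EED])

    # chi_var: smooth contrast variation + sharp-edged blobs, inside mask only
    var = _smooth_field(rng, grid.shape, 0.04 * min(grid.shape)) * phantom.chi_spread_ppm
    ii = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    for _ in range(3):
        idx = np.argwhere(mask.values)
        c = idx[rng.integers(len(idx))]
        r = rng.uniform(0.03, 0.06) * min(grid.shape)
        dist = np.sqrt(sum((ii[a] - c[a]) ** 2 for a in range(3)))
        var[dist <= r] += rng.choice([-1.0, 1.0]) * phantom.chi_spread_ppm * rng.uniform(0.5, 1.0)
    var = np.clip(var, -phantom.chi_spread_ppm, phantom.chi_spread_ppm)
    chi_var = np.where(mask.values, var, 0.0)

    chi_total = chi_stat.values + chi_var
    b_inh = random_inhomogeneity(inh_spec, grid)

    f_base = GAMMA_BAR_HZ_PER_T * phantom.b_base  # main field in Hz
    # the uniform exterior medium is the zero-field baseline: a homogeneous
    # infinite medium produces no internal field, so only susceptibility
    # differences relative to the exterior act as sources (the zero-padded
    # margin then simply continues the exterior medium)
    conv = forward_field_ppm(chi_total - phantom.chi_exterior_ppm, grid, pad_fraction)
    b_sus = (f_base + b_inh.values) * conv * 1e-6
    noise = rng.normal(0.0, noise_sigma, grid.shape) if noise_sigma > 0 else 0.0
    b_obs = b_sus + b_inh.values + noise

    # reference: only internal sources of contrast; exterior (incl. cavities)
    # replaced by the mask-mean internal susceptibility
    mean_internal = chi_total[mask.values].mean()
    chi_ref = np.where(mask.values, chi_total, mean_internal)
    conv_ref = forward_field_ppm(chi_ref - mean_internal, grid, pad_fraction)
    b_ref = f_base * conv_ref * 1e-6
    b_ref = np.where(mask.values, b_ref - b_ref[mask.values].mean(), 0.0)

    return SimulationSample(
        mask=mask,
        chi=SusceptibilityMap(grid, chi_total),
        b_inh=b_inh,
        b_obs=FieldMap(grid, b_obs),
        b_ref=FieldMap(grid, b_ref),
        noise_sigma=noise_sigma,
        seed=phantom.seed,
        labels=labels,
    )


def sample_specs(
    n: int, seed: int, preset: str = "desk-small", **overrides
) -> list[tuple[PhantomSpec, InhomogeneitySpec]]:
    """Per-sample spec pairs with counter-based seed splitting."""
    if preset not in PRESETS:
        raise InvalidInputError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    base = PhantomSpec(matrix=PRESETS[preset], **overrides)
    out = []
    for i in range(n):
        s = (int(seed) * 10007 + i) % (2**31 - 1)
        out.append((replace(base, seed=s), InhomogeneitySpec(seed=s + 1)))
    return out
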