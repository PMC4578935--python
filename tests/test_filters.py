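import numpy as np
import pytest

from mubafire import (
    DegenerateFitError,
    DipfConfig,
    FieldMap,
    InvalidInputError,
    Mask,
    SusceptibilityMap,
    VoxelGrid,
    dipf,
    dipole_kernel,
    forward_field_hz,
    gaussian_background,
    hz_per_ppm,
    polf,
    sphinx_filter,
)
from conftest import ball_mask


def field_on(grid, values):
    return FieldMap(grid, np.asarray(values, dtype=float))


class TestGaussianBackground:
    def test_constant_field_reproduced(self, blob_mask):
        """Mask-restricted weights renormalize: a constant passes through
        exactly even at mask edges."""
        f = field_on(blob_mask.grid, np.full(blob_mask.grid.shape, 4.2))
        bg = gaussian_background(f, blob_mask, sigma=2.0)
        assert np.allclose(bg.values[blob_mask.values], 4.2)
        assert np.all(bg.values[~blob_mask.values] == 0)

    def test_spike_closed_form(self, grid24):
        """Residual at an isolated spike is A*(1 - w0/sum(w)) with w the
        truncated Gaussian weights over the in-mask neighborhood."""
        sigma, A = 1.5, 10.0
        mask = Mask(grid24, np.ones(grid24.shape, dtype=bool))
        vals = np.zeros(grid24.shape)
        vals[12, 12, 12] = A
        bg = gaussian_background(field_on(grid24, vals), mask, sigma)
        radius = int(np.ceil(3 * sigma))
        x = np.arange(-radius, radius + 1)
        w1 = np.exp(-(x**2) / (2 * sigma**2))
        W = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
        expected_bg = A * W.max() / W.sum()  # center weight over total
        assert bg.values[12, 12, 12] == pytest.approx(expected_bg, rel=1e-10)
        resid = A - bg.values[12, 12, 12]
        assert resid == pytest.approx(A * (1 - W.max() / W.sum()), rel=1e-10)

    def test_linear_gradient_interior(self, grid24):
        """Odd moments cancel on a symmetric neighborhood: the background
        equals the field at interior voxels, so the residual vanishes."""
        mask = Mask(grid24, np.ones(grid24.shape, dtype=bool))
        X, _, _ = grid24.coords_mm()
        bg = gaussian_background(field_on(grid24, 3.0 * X), mask, sigma=1.5)
        interior = bg.values[6:-6, 6:-6, 6:-6]
        truth = 3.0 * X[6:-6, 6:-6, 6:-6]
        assert np.allclose(interior, truth, atol=1e-9)

    def test_constant_shift_commutes(self, sphere_mask, rng):
        f = rng.normal(0, 5, sphere_mask.grid.shape)
        bg0 = gaussian_background(field_on(sphere_mask.grid, f), sphere_mask, 2.0)
        bg1 = gaussian_background(field_on(sphere_mask.grid, f + 7.0), sphere_mask, 2.0)
        m = sphere_mask.values
        assert np.allclose(bg1.values[m], bg0.values[m] + 7.0, atol=1e-9)

    def test_invalid(self, sphere_mask):
        f = field_on(sphere_mask.grid, np.zeros(sphere_mask.grid.shape))
        with pytest.raises(InvalidInputError):
            gaussian_background(f, sphere_mask, sigma=0.0)


class TestPolf:
    def test_exact_plane_recovered(self, ellipsoid_mask):
        X, Y, Z = ellipsoid_mask.grid.coords_mm()
        f = field_on(ellipsoid_mask.grid, 5.0 + 2.0 * X - Z)
        coeffs, bg = polf(f, ellipsoid_mask)
        assert np.allclose(coeffs, [5.0, 2.0, 0.0, -1.0], atol=1e-9)
        resid = (f.values - bg.values)[ellipsoid_mask.values]
        assert np.abs(resid).max() < 1e-10

    def test_quadratic_on_symmetric_mask(self, grid24):
        """x^2 on a mask symmetric in x keeps no linear-in-x component; the
        fit matches the normal-equations oracle."""
        mask = ball_mask(grid24, radius=9.5)
        X, Y, Z = grid24.coords_mm(origin=np.array([11.5, 11.5, 11.5]))
        f = field_on(grid24, X**2)
        coeffs, bg = polf(f, mask)
        assert coeffs[1] == pytest.approx(0.0, abs=1e-9)
        idx = np.argwhere(mask.values).astype(float)
        A = np.column_stack([np.ones(len(idx)), idx[:, 0], idx[:, 1], idx[:, 2]])
        oracle = A @ np.linalg.solve(A.T @ A, A.T @ f.values[mask.values])
        assert np.allclose(bg.values[mask.values], oracle, atol=1e-8)

    def test_white_noise_coefficients_small(self, grid24, rng):
        mask = Mask(grid24, np.ones(grid24.shape, dtype=bool))
        f = field_on(grid24, rng.normal(0, 1, grid24.shape))
        coeffs, _ = polf(f, mask)
        # standard error of the gradient terms ~ sigma/(n^0.5 * coord std)
        assert np.abs(coeffs[1:]).max() < 5.0 / (np.sqrt(mask.n_voxels) * 6.9)

    def test_coplanar_mask_degenerate(self, grid24):
        m = np.zeros(grid24.shape, dtype=bool)
        m[:, :, 5] = True  # single plane: z column collinear with intercept
        with pytest.raises(DegenerateFitError):
            polf(field_on(grid24, np.ones(grid24.shape)), Mask(grid24, m))


class TestSphinxFilter:
    def test_order1_equals_polf_on_gradient(self, blob_mask):
        X, Y, Z = blob_mask.grid.coords_mm()
        f = field_on(blob_mask.grid, 1.0 + 0.5 * X - 0.2 * Y + 0.1 * Z)
        bg_s, _ = sphinx_filter(f, blob_mask, order=1, cache=False)
        _, bg_p = polf(f, blob_mask)
        m = blob_mask.values
        assert np.allclose(bg_s.values[m], bg_p.values[m], atol=1e-8)

    def test_removes_exterior_harmonics(self, sphere_mask, rng):
        """A harmonic combination within the fit order is removed to the
        noise floor."""
        from mubafire.ssh_basis import default_spec, raw_basis

        spec = default_spec(sphere_mask, 4)
        raw = raw_basis(spec, sphere_mask.grid)
        field = raw @ rng.normal(0, 30, raw.shape[-1])
        noise = rng.normal(0, 0.3, field.shape)
        f = field_on(sphere_mask.grid, field + noise)
        bg, _ = sphinx_filter(f, sphere_mask, order=4, cache=False)
        resid = (f.values - bg.values)[sphere_mask.values]
        assert resid.std() <= 2 * 0.3

    def test_retains_internal_dipole(self, grid24):
        """A dipole source inside the mask is not harmonic there: most of its
        masked std must survive the harmonic fit."""
        mask = ball_mask(grid24, radius=9.5)
        chi = np.zeros(grid24.shape)
        chi[12, 12, 12] = 1.0
        f = forward_field_hz(SusceptibilityMap(grid24, chi), pad_fraction=0.5)
        in_std = f.values[mask.values].std()
        bg, _ = sphinx_filter(f, mask, order=4, cache=False)
        resid_std = (f.values - bg.values)[mask.values].std()
        assert resid_std > 0.5 * in_std


class TestDipoleKernel:
    def test_magic_angle_zeros_and_bounds(self):
        grid = VoxelGrid((16, 16, 16))
        D = dipole_kernel(grid).spectrum
        assert D[0, 0, 0] == 0.0
        assert D.min() >= -2.0 / 3.0 - 1e-12
        assert D.max() <= 1.0 / 3.0 + 1e-12
        # at kz^2/|k|^2 = 1/3 the kernel vanishes: check a sampled frequency
        # k = (1, 1, 1) has kz^2/k^2 = 1/3 when all spacings are equal
        import scipy.fft as sfft

        kx = sfft.fftfreq(16)
        assert abs(1.0 / 3.0 - kx[1] ** 2 / (3 * kx[1] ** 2)) < 1e-15
        assert abs(D[1, 1, 1]) < 1e-14

    def test_uniform_sphere_analytic(self):
        """Interior field ~0; exterior matches chi/3 * (a/r)^3 (3cos^2 - 1)
        within 5% of the local dipole scale at r >= 2a."""
        grid = VoxelGrid((64, 64, 64), b_base=9.4)
        c = (64 - 1) / 2.0
        ii = np.meshgrid(*[np.arange(64, dtype=float)] * 3, indexing="ij")
        r = np.sqrt(sum((x - c) ** 2 for x in ii))
        a = 8.0
        chi = np.where(r <= a, 1.0, 0.0)
        f = forward_field_hz(SusceptibilityMap(grid, chi), pad_fraction=0.5)
        cos2 = ((ii[2] - c) / np.where(r > 0, r, 1.0)) ** 2
        analytic = hz_per_ppm(9.4) * (chi.max() / 3.0) * (a / np.where(r > 0, r, 1)) ** 3 * (3 * cos2 - 1)
        shell = (r >= 2 * a) & (r <= 3 * a)
        scale = np.abs(analytic[shell]).max()
        assert np.abs(f.values[shell] - analytic[shell]).max() <= 0.05 * scale
        interior = r <= 0.7 * a
        surface_scale = hz_per_ppm(9.4) * chi.max()
        assert np.abs(f.values[interior]).max() <= 0.05 * surface_scale

    def test_point_source_zero_angular_mean(self):
        """The dipole field averages to ~0 over a centered shell."""
        grid = VoxelGrid((48, 48, 48))
        chi = np.zeros(grid.shape)
        chi[23, 23, 23] = 1.0
        f = forward_field_hz(SusceptibilityMap(grid, chi), pad_fraction=0.5)
        c = 23.0
        ii = np.meshgrid(*[np.arange(48, dtype=float)] * 3, indexing="ij")
        r = np.sqrt(sum((x - c) ** 2 for x in ii))
        shell = (r >= 8) & (r <= 10)
        shell_scale = np.abs(f.values[shell]).max()
        assert abs(f.values[shell].mean()) <= 0.02 * shell_scale

    def test_forward_field_zero_mean(self, rng):
        """D(0)=0 makes any forward field mean-free over the padded volume."""
        grid = VoxelGrid((20, 22, 18))
        chi = rng.normal(0, 0.5, grid.shape)
        from mubafire.filters import forward_field_ppm, pad_widths
        import numpy as _np

        pads = pad_widths(grid.shape, 1.0 / 8.0)
        padded = _np.pad(chi, [(p, p) for p in pads])
        pgrid = VoxelGrid(padded.shape)
        D = dipole_kernel(pgrid).spectrum
        import scipy.fft as sfft

        full = sfft.irfftn(D * sfft.rfftn(padded), s=padded.shape)
        assert abs(full.mean()) <= 1e-12 * np.abs(full).std()


@pytest.fixture(scope="module")
def dipf_setup():
    """64^3 scene with one near-exterior and one interior point source."""
    grid = VoxelGrid((64, 64, 64), b_base=9.4)
    mask = ball_mask(grid, radius=18.0)
    chi_ext = np.zeros(grid.shape)
    chi_ext[31, 31, 51] = 5.0  # just outside the mask surface
    chi_int = np.zeros(grid.shape)
    chi_int[31, 31, 31] = 5.0  # center of the mask
    f_ext = forward_field_hz(SusceptibilityMap(grid, chi_ext), pad_fraction=1 / 8)
    f_int = forward_field_hz(SusceptibilityMap(grid, chi_int), pad_fraction=1 / 8)
    return grid, mask, f_ext, f_int


class TestDipf:
    def test_zero_field_fixed_point(self, sphere_mask):
        f = field_on(sphere_mask.grid, np.zeros(sphere_mask.grid.shape))
        res = dipf(f, sphere_mask, DipfConfig(n_iter=5))
        assert np.all(res.chi_ext.values == 0)
        assert np.all(res.background.values == 0)

    def test_exterior_source_self_consistency(self, dipf_setup):
        """With the Tikhonov term switched off the fit inverts its own
        forward model: an exterior-source field is removed almost entirely."""
        grid, mask, f_ext, _ = dipf_setup
        res = dipf(f_ext, mask, DipfConfig(lambda_tik=0.0))
        m = mask.values
        resid = f_ext.values[m] - res.background.values[m]
        assert resid.std() <= 0.05 * f_ext.values[m].std()
        assert np.all(res.chi_ext.values[m] == 0)  # support excludes interior

    def test_interior_source_retained(self, dipf_setup):
        grid, mask, _, f_int = dipf_setup
        res = dipf(f_int, mask, DipfConfig())
        m = mask.values
        resid = f_int.values[m] - res.background.values[m]
        assert resid.std() >= 0.80 * f_int.values[m].std()

    def test_residual_history_non_increasing(self, dipf_setup):
        grid, mask, f_ext, _ = dipf_setup
        res = dipf(f_ext, mask, DipfConfig(n_iter=30))
        h = res.residual_history
        after = h[3:]
        assert np.all(np.diff(after) <= 1e-9 * h[0])

    def test_homogeneity_exact(self, dipf_setup):
        """CG iterates are exactly degree-1 homogeneous in the data."""
        grid, mask, f_ext, _ = dipf_setup
        cfg = DipfConfig(n_iter=10)
        b1 = dipf(f_ext, mask, cfg).background.values
        b3 = dipf(field_on(grid, 3.0 * f_ext.values), mask, cfg).background.values
        assert np.allclose(b3, 3.0 * b1, atol=1e-9 * np.abs(b3).max())

    def test_additivity_at_convergence(self, dipf_setup):
        """Finite-iteration CG is only approximately additive; for two
        well-converged exterior-source fields the superposition holds to ~2%."""
        grid, mask, f_ext, _ = dipf_setup
        chi2 = np.zeros(grid.shape)
        chi2[31, 10, 31] = 5.0
        f2 = forward_field_hz(SusceptibilityMap(grid, chi2), pad_fraction=1 / 8)
        cfg = DipfConfig()
        b1 = dipf(f_ext, mask, cfg).background.values
        b2 = dipf(f2, mask, cfg).background.values
        both = field_on(grid, 2.0 * f_ext.values - 0.5 * f2.values)
        b12 = dipf(both, mask, cfg).background.values
        scale = np.abs(b12[mask.values]).max()
        assert np.abs(b12 - (2.0 * b1 - 0.5 * b2))[mask.values].max() <= 0.02 * scale

    def test_invalid_inputs(self, sphere_mask):
        vals = np.zeros(sphere_mask.grid.shape)
        with pytest.raises(InvalidInputError):
            DipfConfig(n_iter=0)
        vals[sphere_mask.values] = np.nan
        with pytest.raises(InvalidInputError):
            dipf(field_on(sphere_mask.grid, vals), sphere_mask, DipfConfig(n_iter=2))
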