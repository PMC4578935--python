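# Methods

## Field model and units

A gradient-echo voxel accumulates phase φ = γ·b·t_TE, so the local field
offset b (Hz) is the slope of unwrapped phase versus echo time divided by
2π (`core.field_from_phase`; unweighted ordinary least squares over echoes,
plain division for a single echo). The measured field decomposes as
b = b_dist + b_int: distortions from sources outside the volume of interest
(VOI) plus the internal, tissue-generated field that downstream QSM needs.

All fields are carried in Hz and susceptibilities in ppm. The conversion is
Δf = (γ/2π)·B_base·χ·10⁻⁶ with γ/2π = 42.577478518 MHz/T
(`core.GAMMA_BAR_HZ_PER_T`); at the default B_base = 9.4 T, 1 ppm ↔
400.2 Hz. Voxel coordinates are 0-based indices times voxel size; only
relative coordinates enter any computation, so half-voxel conventions are
immaterial.

## The filters

**Gaussian (GF).** Homodyne-style high-pass: the background estimate at a
voxel is the Gaussian-weighted mean of the field over *in-mask* voxels
within a kernel truncated at 3σ (σ in voxels; truncation keeps >99.7% of
kernel mass), implemented as separable truncated convolutions of field·mask
and mask with renormalization. Mask-aware weighting avoids edge leakage but
the filter has no physical source model and erodes genuine contrast — it is
included as the conventional baseline.

**POLF.** Least-squares plane a + b·x + c·y + d·z over masked voxels,
solved on centered/scaled coordinates for conditioning and mapped back.
Only 1st order: higher polynomial orders do not correspond to solutions of
the static-field problem.

**SPHINX.** Real regular solid spherical harmonics v_lm = (r/R)^l·Y_lm
(orthonormal real Y_lm without Condon–Shortley phase; the sign convention is
unobservable in the corrected field) are evaluated on the grid and
orthonormalized on the masked domain under the voxelwise inner product.
The basis is centered on the mask center of mass with the radial scale R set
to the maximum masked-voxel distance, keeping r^l ≤ 1 and the high orders
conditioned. Orthonormalization is per-vector classical Gram–Schmidt with
one re-orthogonalization pass (CGS-2), which holds the Gram residual below
10⁻⁸ up to order 10 on every mask geometry tested (sphere, ellipsoid,
irregular blob, mask with interior holes); a vector whose post-subtraction
norm falls below 10⁻¹⁰ of its original norm raises a degenerate-basis error.
Because Gram–Schmidt is sequential, the leading (n+1)² columns of an
order-N basis *are* the order-n basis — bases are cached per mask and
truncated, which makes order sweeps and the in-chain order-4 fit cheap.
The l = 0 (constant) term is built and fitted as well; the chain's POLF
stage has already removed offsets, and the evaluation statistics are
mean-insensitive, so it is harmless.

**DIPF.** Susceptibility-induced fields are dipole convolutions; in k-space
the unit dipole response is D(k) = 1/3 − k_z²/|k|² (z along B0), with
D(0) := 0 since susceptibility differences leave the mean field
undetermined. The filter estimates an exterior pseudo-susceptibility by

  min_χ ‖m·[b − C(χ * d)]‖₂² + λ‖χ‖₂²,  C = (γ/2π)·B_base·10⁻⁶,

solved by conjugate gradients on the normal equations, fixed 50 iterations,
initialized at χ = 0, no preconditioner or stopping tolerance. χ is
constrained to the mask exterior by hard support projection each step (the
printed Tikhonov weight W_T = m would penalize only interior values of a
quantity that is zero there by definition; hard restriction realizes that
intent, and a config flag `hard_support=False` restores the literal soft
reading). The volume is zero-padded by 1/8 per side and the
pseudo-susceptibility may occupy the padded margin (`allow_pad_sources`).
The convolution is spectral (rfft) — exact in the continuum limit and
O(N log N), against which a truncated real-space kernel has no advantage.

λ defaults to 500 *in the Hz-field / ppm-susceptibility convention of this
package*. This matters: λ penalizes the ppm amplitude of the exterior
solution, which is precisely what stops large-amplitude near-surface dipole
layers from mimicking fields of truly distant sources. It also means
exterior-source fields are never removed completely — Tikhonov shrinkage is
scale-invariant, so even a noiseless exterior point-source field retains a
few percent (extended adjacent sources) to ~20% (single remote voxels) of
its masked std at any iteration count. With λ → 0 the filter inverts its
own forward model almost exactly, but then the standalone DIPF becomes
indistinguishable from the full chain on simulated data, which contradicts
the observed behavior of dipole filtering; the λ = 500 convention
reproduces it. This trade-off is the package's single most consequential
design choice.

## The chain

POLF → SPHINX (order 4) → DIPF, each applied to the residual of the
previous stage; all stage backgrounds are retained and the decomposition
`input − Σ backgrounds = corrected` is exact to machine precision. The
in-chain DIPF fits on the original mask (no boundary erosion). The optional
local stage then:

1. thresholds at ξ = n_σ·σ(b̃) (n_σ default 8, typical 5–15; σ taken over
   the original mask of the chain-corrected field),
2. bridges diagonal-neighbor outliers — for excluded voxels differing by one
   step along each of two axes the two face-bridging voxels are added; for
   three-axis diagonals the three single-axis bridges (a natural extension
   of the two-axis rule) — then adds every in-mask face neighbor
   (six-neighbor erosion of the retained mask), in a single pass,
3. runs a DIPF whose solution support is exactly the excluded set and whose
   data term is evaluated on mask minus exclusion, and subtracts the
   resulting field.

Excluded voxels are reported as missing in the final map, not inpainted:
their field values are not representative data.

## The simulation

Each Monte Carlo sample combines:

* **Phantom** (`simulate.make_phantom`): a smoothly perturbed ellipsoid
  (semi-axes 0.31 of the matrix, ±6% smooth radial perturbation) strictly
  inside the volume; tissue χ = −9 ppm plus a smooth ±0.2 ppm texture;
  4 thin vessel tubes at −7.9 ppm; 2 central ventricle blobs at −9 ppm;
  exterior −6 ppm; 3 air-like cavities (+0.4 ppm) tangent to the outer
  surface. Structure sizes scale with the matrix, so the desk-scale preset
  (72×80×56) is geometrically similar to the full preset (138×162×106).
* **Inhomogeneity** (`simulate.random_inhomogeneity`): solid harmonics up to
  order 4 (shim-like; the order is configurable) with Gaussian random
  coefficients decaying as 1/(l+1), rescaled so the volume maximum equals
  the 400 Hz bound exactly.
* **Observation**: b_obs = [f_base + b_inh]·(d * χ)·10⁻⁶ + b_inh + noise,
  f_base the main field in Hz, noise Gaussian with σ = 0.3 Hz. The
  multiplicative b_inh factor is applied pointwise after the convolution;
  its effect is at the b_inh/B_base ≈ 10⁻⁶ relative level and a test pins
  its placement. The convolution acts on χ minus the exterior value: a
  homogeneous infinite medium generates no internal field, so only
  susceptibility differences relative to the surrounding medium are sources
  and the zero-padded margin simply continues that medium.
* **Reference**: b_ref re-runs the convolution with the exterior replaced by
  the mask-mean internal χ (cavities count as exterior) and removes the
  masked mean — the ground-truth internal contrast.

Every sample is bit-reproducible from its two spec seeds; study seeds are
split from a global seed by a counter scheme.

The phantom replaces a measured post-mortem anatomy template that is not
distributable. Free structural parameters (vessel count/radius, texture
correlation length, cavity sizes) were fixed once so that the reference
field's masked σ sits in the ~6 Hz range of the full-scale study
(desk-scale draws give ≈ 6.3–7.3 Hz) and then frozen. What the phantom does
not emulate: real cortical folding and sulcal air proximity, vessel trees
(only straight segments), anisotropic voxels, phase-unwrapping failures,
and coil-dependent noise correlations — so quantitative agreement with
measured-brain statistics is expected only in ordering and scale, not in
exact values.

## Evaluation

The accuracy metric is L1 = (1/n)·Σ_mask |b_corr − b_ref| with both maps
mean-removed over the mask (the printed form of the metric omits the
absolute value, but as a signed sum of mean-removed maps it would be ≈ 0
identically; the absolute value is the meaningful reading). The masked σ of
the corrected map is the reference-free companion statistic; across filters
and samples it correlates strongly (r ≈ 1.0 in the desk study) with L1,
which is what makes σ a usable quality proxy on measured data. Parameter
sweeps report mean L1 normalized by the reference σ (dimensionless,
monotone-equivalent to L1; the normalization choice is the package's own)
and wall time, which is reported but never asserted on.

At desk scale (10 seeds) the study reproduces the expected pattern: mean L1
ordering SPHINX > GF > DIPF > MUBAFIRE (≈ 15.2 > 13.7 > 3.6 > 3.1 Hz at
seed 1), the chain's mean σ within ~20% of the reference σ, and the
Gaussian filter's σ several times the reference. Standalone SPHINX misses
the cavity dipole fields entirely; the Gaussian filter destroys contrast
and produces edge artifacts; DIPF under-fits the smooth long-range part by
its regularization floor; the chain lets each stage handle the component it
models.

## Numerical choices and degenerate inputs

* FFTs via `scipy.fft` real transforms; padded shapes are the input shape
  times 1 + 2/8, rounded up per axis.
* CG residual history records the data-term norm per iteration; it is
  non-increasing after the initial transient and asserted so in tests.
* Histograms are fixed-width in Hz with a configurable bin count
  (quantile binning would hide the tails the local stage targets).
* Empty masks, non-increasing echo times, |m| > l, coplanar fit domains,
  NaNs inside the mask, and a local exclusion that swallows the whole mask
  all raise typed errors (`InvalidInputError`, `DegenerateBasisError`,
  `DegenerateFitError`).
* Population (divisor-n) standard deviations throughout.

## Known limitations

* The λ = 500 Hz/ppm regularization floor means standalone DIPF retains a
  few percent of even ideal exterior-source fields (see above); the chain
  inherits a milder version of this through its final stage, which leaves
  its corrected σ slightly above the reference contrast at desk scale.
* SPHINX beyond order ~10 is expensive ((n+1)² basis volumes and an
  O(n⁴·n_voxels) orthonormalization); the practical ceiling is order 15.
* The local stage assumes outliers are sparse; exclusion sets covering a
  large mask fraction degrade the fit domain and eventually error out.
* Phase unwrapping, brain extraction and multi-coil combination are out of
  scope; inputs are assumed unwrapped, masked and in Hz (or unwrapped
  radians with echo times).
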