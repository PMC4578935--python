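# mubafire

Multistage background field removal for MR field maps.

Gradient-echo phase measures the local magnetic field b(r) in each voxel.
For quantitative susceptibility mapping (QSM) and phase-contrast studies the
interesting part is the *internal* field b_int generated by tissue
susceptibility inside the volume of interest; it is buried under background
distortions b_dist an order of magnitude stronger — static-field (B0)
inhomogeneity, shim imperfections, and fields from air/tissue interfaces and
other sources outside the brain mask:

    b = b_dist + b_int

`mubafire` separates the two with a sequential chain of physically motivated
filters, each targeting the class of distortion it models best:

1. **POLF** — 1st-order polynomial fit (constant offset + linear gradients).
2. **SPHINX** — projection onto real regular solid spherical harmonics
   r^l Y_lm, Gram–Schmidt-orthonormalized on the (arbitrary) brain mask.
   Background fields are source-free inside the mask, hence harmonic; a
   low-order expansion (order 4 in the chain, 10 standalone) captures the
   smooth long-range part.
3. **DIPF** (projection onto dipole fields) — fits an exterior
   pseudo-susceptibility χ_ext whose dipole-convolved field
   b_dist ≈ B0·(χ_ext * d), d(k) = 1/3 − k_z²/|k|², best explains the masked
   field, by conjugate gradients with Tikhonov regularization
   (λ = 500, 50 iterations, 1/8 zero padding):

       min_χext ‖m·[b − B0(χ_ext * d)]‖₂² + λ‖χ_ext‖₂²

4. **Local stage** (optional) — thresholds the corrected map at
   ξ = n_σ·σ(b̃), connects diagonal-neighbor outliers, applies six-neighbor
   erosion, and removes the dipole field radiated by the excluded pockets
   (air bubbles, intra-voxel-dephasing outliers) with a support-restricted
   DIPF.

The package also ships the Monte Carlo validation machinery: a brain-like
susceptibility phantom (tissue −9 ± 0.2 ppm, vessels −7.9 ppm, ventricles
−9 ppm, exterior −6 ppm, positive-χ air cavities), randomized harmonic
inhomogeneities bounded at ±400 Hz, Gaussian field noise σ = 0.3 Hz, and the
evaluation metrics (masked L1 deviation from the mean-removed internal
reference field, masked σ, parameter sweeps, L1–σ correlation).

## Worked example

```python
import numpy as np
from mubafire import (ChainConfig, masked_sigma, l1_metric, run_chain,
                      sample_specs, simulate_sample)

pspec, ispec = sample_specs(1, seed=42)[0]       # one Monte Carlo draw
sample = simulate_sample(pspec, ispec)            # b_obs, mask, b_ref, chi
result = run_chain(sample.b_obs, sample.mask, ChainConfig())
print(f"observed field sigma : {masked_sigma(sample.b_obs, sample.mask):6.2f} Hz")
for name, bg in result.stage_backgrounds.items():
    print(f"stage {name:<7s} removes: {masked_sigma(bg, sample.mask):6.2f} Hz (std)")
print(f"corrected field sigma: {masked_sigma(result.corrected, sample.mask):6.2f} Hz")
print(f"reference field sigma: {masked_sigma(sample.b_ref, sample.mask):6.2f} Hz")
print(f"L1 vs reference      : {l1_metric(result.corrected, sample.b_ref, sample.mask):6.2f} Hz")
```

prints

```
observed field sigma :  44.59 Hz
stage polf    removes:  15.02 Hz (std)
stage sphinx  removes:  16.47 Hz (std)
stage dipf    removes:  34.96 Hz (std)
corrected field sigma:   8.27 Hz
reference field sigma:   7.05 Hz
L1 vs reference      :   3.04 Hz
```

The simulated 72×80×56 field map carries ~45 Hz of masked variation, almost
all of it background; the chain strips the plane, the smooth harmonics and
the exterior dipole fields, leaving a map whose spread (8.3 Hz) is close to
the true internal contrast (7.1 Hz) and whose mean absolute deviation from
the ground-truth internal field is ~3 Hz.

## Command line

```sh
mubafire correct  --in field.nii.gz --mask mask.nii.gz \
                  --out corrected.nii.gz --method mubafire --save-stages
mubafire simulate --preset desk-small --n 10 --seed 1 --out sim/
mubafire study    --preset desk-small --n 10 --seed 1 --out study/
mubafire sweep    --n 3 --seed 1 --out sweep/
```

Fields and masks are NIfTI volumes (fields in Hz, masks uint8 {0,1}); every
run writes a JSON manifest with its configuration and seed.

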