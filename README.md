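# fibrest

Structure-tensor orientation analysis and deterministic tractography for 3D
white-matter microscopy volumes — with a synthetic phantom generator so the
whole pipeline is testable without multi-gigabyte imaging data.

## Who this is for

Synchrotron phase-contrast tomography (and comparable 3D microscopy) of
osmium-stained white matter shows myelinated axons as dark tubes at voxel
sizes of 75–550 nm. At that resolution one can ask questions that diffusion
MRI can only model indirectly: how are axonal fasciculi oriented, how
dispersed are they, how do they bend around cells and blood vessels?
`fibrest` implements the image-analysis chain for those questions:

1. **Scale-space 3D structure tensor.** Per voxel,
   `S = G_ρ * (∇I_σ ∇I_σᵀ)` where `∇I_σ` is the Gaussian-derivative gradient
   at scale σ and `G_ρ` aggregates over a neighbourhood ("patch") of scale ρ.
   The raw eigenvalues λ₁* ≥ λ₂* ≥ λ₃* (normalised to Σλ* = 1) are converted
   to a diffusion-like tensor with the single-parameter model
   `λᵢ = exp(−λᵢ*/γ)` (then renormalised), so the principal eigenvector is
   the fibre direction and the usual fractional anisotropy
   `FA = sqrt(3/2 · Σ(λᵢ−λ̄)² / Σλᵢ²)` applies. Across a suite of (σ, ρ)
   *scales*, each voxel keeps the scale with the largest scale-normalised FA:
   `d_j = argmax_i (FA_ji / max_j FA_ji)`.
2. **Orientation statistics.** Principal directions (axial: v ≡ −v) are
   binned into an area-normalised spherical histogram (the fibre orientation
   distribution, FOD), and summarised with an antipodally symmetric Bingham
   fit `p(x) ∝ exp(−κ₁(a₁·x)² − κ₂(a₂·x)²)`: the orientation dispersion
   index `ODI = (2/π)·arctan(1/√(κ₁κ₂))` and dispersion anisotropy
   `DA = (2/π)·arctan((κ₁−κ₂)/κ₂)`, both in [0, 1]. FA distributions are
   reported as kernel-density estimates with median/IQR.
3. **FACT tractography.** Deterministic fibre-assignment-by-continuous-
   tracking on the per-voxel principal direction, with seed / inclusion /
   rejection ROI masks, then QuickBundles clustering (minimum average
   direct-flip distance, running centroids) into "fasciculus" centroids.
4. **Streamline shape metrics.** Tortuosity `τ = L/d` (path length over
   endpoint chord, ≥ 1) and maximum deviation `d_max` (largest orthogonal
   distance of interior points from the chord, in μm), compared between
   groups with two-sample Kolmogorov–Smirnov, Wilcoxon rank-sum, and
   Brown–Forsythe tests at α = 0.05.
5. **Phantoms.** Anti-aliased renderings of parallel, laminar (inclined
   slabs), and crossing fibre populations with ground-truth orientations and
   centrelines; bright cell bodies and blood vessels that deflect fibres;
   demyelinated regions with reduced contrast; additive Gaussian noise.
   Everything is reproducible bit-for-bit from (spec, seed).

## Worked example

```python
from fibrest import (PhantomSpec, ScaleParams, analyse_volume,
                     build_parallel_fibre_volume, extract_principal_directions,
                     fit_bingham, fa_density)
from fibrest.volume import ROIMask

spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size=1000.0, rng_seed=1)
vol, truth = build_parallel_fibre_volume(spec)     # dark tubes along +x
eigen, dominant = analyse_volume(vol, ScaleParams(scales=((1.0, 4.0),),
                                                  gamma=0.3))
fibre = ROIMask(truth.labels > 0, vol.voxel_size, "fibre")
directions, fa = extract_principal_directions(eigen, include=fibre)
fit = fit_bingham(directions)
print(f"ODI={fit.odi:.4f}  DA={fit.da:.2f}")
print(fa_density(fa).report())
```

prints

```
ODI=0.0001  DA=0.00
mean±sd: 0.78±0.00, median/IQR: 0.78/0.00 (n=39408)
```

An ODI of 1e-4 says the recovered fibre directions are essentially
perfectly aligned, and a DA of 0 that their (negligible) spread is
circular — as expected for a noiseless parallel phantom. The FA median of
0.78 is the anisotropy of the converted tensor at γ = 0.3 inside fibres;
its IQR collapses to 0 because every fibre voxel sees the same ideal tube
geometry. The full pipeline (phantom → tensors → FOD/Bingham →
tracking → bundle metrics) is one call, `fibrest.run_pipeline(config)`, or
from the shell:

```bash
fibrest run --preset parallel --seed 1 --out runs/parallel
fibrest phantom --preset crossing --out phantom_dir --seed 2
fibrest st --in phantom_dir/volume.nii.gz --out st_dir --sigma 1 --rho 4 --gamma 0.3
```

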