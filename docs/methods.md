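# Methods

This note documents the models, conventions, and numerical choices behind
`fibrest`, and what the synthetic phantoms do and do not establish about
real imaging data.

## Conventions

Volumes are `(z, y, x)`-indexed arrays with an isotropic voxel size stored
in nanometres; direction vectors and streamline coordinates use `(x, y, z)`
component order in micrometres, with voxel centres at integer multiples of
the voxel size. Orientations are axial — `v` and `−v` are the same
direction — and every angular comparison uses the acute angle
`min(∠, 180°−∠)`. Eigenvectors carry a deterministic sign (first nonzero
component positive) so outputs are reproducible bit-for-bit.

## Structure tensor

The tensor is computed in three separable-filtering steps: Gaussian(σ)
derivative gradients, per-voxel outer product, Gaussian(ρ) aggregation.
Boundary handling is mirror reflection, and voxels within one ρ-kernel
radius of the border are flagged and excluded from statistics by default.
Kernels are truncated at radius `ceil(2ρ)` voxels (derivative kernels at
`ceil(4σ)`); the physical "kernel size" quoted for a configuration is the
full width `(2·ceil(2ρ)+1) ·` effective voxel size, which reproduces the
sizes of all five reference imaging configurations bundled in
`validation.KERNEL_CONFIGS` (12.1, 9.2, 2.0, 18.7, 9.4 μm). Downsampling
before analysis is plain block averaging; the effective voxel size is the
native size times the factor.

**Eigenvalue conversion.** Raw eigenvalues are clipped at zero and
normalised to sum to 1 *before* the γ conversion `λᵢ = exp(−λᵢ*/γ)`; the
normalisation makes γ dimensionless and transferable across volumes, so a
single γ (default 0.30, sensible range 0.25–0.35) can serve one sample.
Because `exp(−x/γ)` is decreasing, conversion reverses the ordering: the
fibre direction is the eigenvector of the *smallest* raw eigenvalue, paired
with the largest converted one. Voxels whose tensor trace is below
`1e−12 ×` the volume's intensity variance are flagged as zero tensors
(placeholder isotropic eigenvalues, FA = 0, excluded from statistics).

**Scale-space selection.** Tensors are recomputed per (σ, ρ) scale from the
same volume (no pyramid resampling). Each scale's FA map is normalised by
that scale's maximum FA over all voxels; per voxel the largest normalised
FA wins, ties going to the lowest scale index. A scale with an all-zero FA
map contributes score 0 (logged), never a division error. The default scale
suite (ρ from 5.5 down to 1.0 voxels with paired σ) matches the published
multi-scale configuration; for the bundled two-region selectivity
experiment a deliberately wide pair, (σ, ρ) = (0.5, 1) and (3, 6) voxels,
is used instead.

## Orientation statistics

The FOD is a spherical histogram over the hemisphere around a pole axis —
chosen (or auto-chosen by minimising mean |v·axis|) as the axis with the
least directional contribution, so no mass sits at the parametrisation's
degenerate pole. Bins are 5° in azimuth and elevation by default (resolving
a 35° laminar separation with margin); the pole cap is a single bin to
avoid azimuth degeneracy, and each bin's probability density is
`count/(n·Δω)` with Δω its exact solid angle, so `Σ p·Δω = 1` always.

The Bingham fit takes its axes from the eigen-decomposition of the
orientation scatter matrix `S = (1/n)Σ vvᵀ` (mean axis = largest
eigenvalue) and its concentrations κ₁ ≥ κ₂ ≥ 0 from maximum likelihood,
with the normalising constant reduced to a smooth 1D integral (the azimuth
integral is a Bessel-I₀ term) evaluated by adaptive quadrature; κ is capped
at 1e4, and a scatter matrix with three near-equal eigenvalues short-
circuits to κ₁ = κ₂ = 0 with a degeneracy flag. The dispersion indices use
the closed forms `ODI = (2/π)·arctan(1/√(κ₁κ₂))` and
`DA = (2/π)·arctan((κ₁−κ₂)/κ₂)`. These forms satisfy the published
qualitative contract — both in [0, 1], ODI → 0 for aligned populations,
DA = 0 for circular spread and 1 for planar spread — but the original
toolbox's exact algebra is not public, so absolute ODI/DA values from other
software may differ numerically; comparisons should be within one
implementation. ODI and DA are only meaningful for single-pathway FODs.

FA distributions use a Gaussian KDE (Scott's rule by default) evaluated on
[0, 1] and renormalised there; summaries are reported as mean ± sd and
median/IQR.

## Tractography and bundles

FACT propagates piecewise-linearly to the exit face of each voxel along
that voxel's axial direction, sign-aligned to keep the turning angle acute;
it is parameter-free apart from termination rules. Defaults: angle
threshold 60°, minimum length 10 voxels, bidirectional seeding at voxel
centres (or jittered for densities > 1). Exactly-on-face positions advance
into the larger-index voxel, deterministically. Seeds outside the tracking
mask are skipped with a log entry; zero-direction voxels terminate the
streamline.

QuickBundles is the single-pass sequential rule: each streamline (resampled
to K = 18 points) joins the nearest existing bundle if its running
flip-aligned centroid is within the MDF threshold, else founds a new
bundle. The threshold is per-run configuration (it depends on sample
geometry and is always logged). Shape metrics are computed on bundle
centroids by default: tortuosity τ = L/d and maximum deviation d_max over
interior points i = 2..N−1 (N ≤ 2 gives d_max = 0; coincident endpoints
leave both metrics undefined/NaN and excluded with a log entry). "argmax"
in the d_max definition is read as the maximum *distance value*, matching
its description as the largest physical deviation. Group comparisons run
two-sample KS, two-sided Wilcoxon rank-sum, and Brown–Forsythe (Levene
with median centring), with decisions at α = 0.05.

## Phantoms: what they emulate, and what they don't

Fibres are rendered as anti-aliased dark tubes (intensity = background −
gap × voxel coverage) on a brighter background, matching the appearance of
osmium-stained myelin in phase-contrast reconstructions and leaving
sub-voxel gradient information at the walls for the structure tensor.
Geometry defaults follow the reported anatomy: fibre radii of a few μm at
~0.5–1 μm voxels, laminae 5–45 μm thick with inclinations up to ~35°,
crossings near 90°, cell radii 2.5–7 μm, vessel radii 5–15 μm. Obstacles
deflect centrelines radially with `d(r) = R·(R+h−r)/h` inside the halo
(clipped to R), applied in the plane perpendicular to the fibre axis — a
stand-in rule whose *amplitude* (deviations on the scale of the obstacle
radius, up to ~12 μm for vessels) is anchored to observation, while its
functional shape is a modelling convenience. Demyelination multiplies the
local fibre/background gap by a contrast factor and adds bright cells at a
given density, leaving true orientations untouched.

The two-region scale-selectivity phantom deserves a note: a *noiseless,
perfectly parallel* two-radius phantom is scale-degenerate — per-tensor
eigenvalue normalisation makes FA independent of kernel size when every
gradient in the kernel shares one orientation, so no FA-based scale
selection can separate the regions. Realistic small-axon tissue is not like
that: small axons are densely packed, carry micro-dispersion of the order
of 10–20°, and sit among a higher density of cells. The canonical
`build_scale_test_volume` therefore gives the thin-fibre band 15° direction
jitter, 2.5 μm spacing, and ~10% cell volume, and keeps the thick-fibre
band clean. With that, the coarse scale's σ washes out thin-tube contrast
(cell surfaces dominate its response) while the fine scale sees nothing but
noise deep inside thick fibres — and the dominant-scale map separates the
regions. Passing this test shows the selection rule behaves as designed
under those conditions; it does not certify scale selection on tissue whose
contrast structure differs from the phantom's.

More generally the phantoms omit physics the real data has: phase-retrieval
artefacts, detector blur, intensity inhomogeneity, vacuoles, and curved
macroscopic pathway geometry. Tests passing on phantoms validate the
*algorithms* and their implementations, not acquisition-specific behaviour.

## Numerical and degenerate-input choices

- Gaussian KDE bandwidth: Scott's rule; degenerate inputs (< 2 distinct
  values) return a flagged summary without a curve.
- Bingham quadrature tolerance 1e−8 relative; optimisation L-BFGS-B with a
  moment-based initial guess `κᵢ ≈ 1/(2·E[(aᵢ·x)²])`.
- The statistical calibration experiment uses 4000 replicates: the exact
  two-sample KS test is discretely conservative at n = 50 (true level
  ≈ 0.035), and the replicate count keeps the Monte Carlo error (~0.003)
  small enough that the measured rate reflects the test rather than the
  draw.
- Streamline tracking advances an epsilon (1e−6 voxel) past each face to
  avoid re-entering the voxel just left.
- Repeated eigenvalues are ordered deterministically by the eigenvector
  sign convention; numerically zero tensors go to the zero mask rather than
  producing arbitrary eigenvectors.

## Problem sizes

The validation experiments run on one CPU in a few minutes total:
orientation recovery on a 128³ phantom at 1 μm voxels, crossing/laminar
experiments at 64³, the scale-selectivity phantom at 96³ with 0.5 μm
voxels, tractography experiments at 64³ (one seed slice), and a full 128³
pipeline run. These sizes were chosen as the smallest grids on which each
geometric feature (kernel support, lamina count, halo width) is comfortably
resolved.

## Known limitations

- Isotropic voxels only; no streaming or chunked filtering for
  larger-than-memory volumes.
- No probabilistic tracking or sub-voxel direction interpolation; FACT uses
  one direction per voxel.
- No multi-peak FOD decomposition into per-pathway Bingham mixtures, so
  ODI/DA on crossing regions are reported but not interpretable.
- The Bingham ODI/DA closed forms are implementation-defined (see above).
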