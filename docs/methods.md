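# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Phantom signal model

The phantom is geometric, not anatomical: the brainstem is an axis-aligned
ellipsoid (default semi-axes 3.0 × 2.0 × 2.0 mm) and the three motor nuclei
are spheres with the study's ROI diameters (V 1.4 mm, VII 1.2 mm,
XII 1.1 mm) placed inside it, on a 64 × 48 × 48 grid of 0.1 mm isotropic
voxels. Anatomy is irrelevant to verifying the arithmetic; every geometric
element is configurable.

Per-voxel signals follow the generating equations of each acquisition:

| condition | model |
|---|---|
| T2 | S = base × fold(region); fold ≥ 1 in disease regions |
| DWI (dir, b) | S = base × exp(−b·D_dir(region)), b ∈ {125, 500, 1000} s/mm² |
| MT pair | S_on = S_off × (1 − MTR(region)) |
| Gd pair | S_post = S_pre × (1 + E(region)) |
| T2* | base, with injected clusters at depth × in-mask mean |

Default truth values are an end-stage disease brainstem: T2 fold changes
{V: 8, VII: 15, XII: 5} — the literature on this model reports up to roughly
15-fold hyperintensity at end stage, largest in the facial nucleus, so the
preset puts the extreme in VII; ADC 0.7×10⁻³ mm²/s in normal brainstem
falling to 0.50–0.55×10⁻³ in the nuclei (vacuolated tissue shows restricted
diffusion); MTR 0.35 falling to 0.25–0.28; enhancement 0 everywhere (the
blood–brain barrier stays intact in this model). Fold changes below 1 in
disease regions are rejected as specification errors.

MPIO clusters are digital balls: the n in-mask voxels nearest the requested
centre, written at `depth × (pre-injection in-mask mean)`. Expressing depth
as a fraction of the mask mean makes detector threshold behaviour directly
controllable: depth 0.4 is unambiguously below a 0.65 threshold fraction. A
cluster whose ball would cross the tissue boundary, or overlap a previous
cluster, is rejected with a diagnostic rather than silently truncated.

Noise is applied last. Rician noise, `sqrt((S+n₁)² + n₂²)` with
n ~ N(0, σ²), is the default for magnitude-reconstructed MRI; pure Gaussian
is available for linear-regime tests. The zero-signal background of a Rician
image is Rayleigh with mean σ√(π/2), which the tests verify to 2% at 10⁵
voxels. Identical spec + seed gives bit-identical output (one
`numpy.random.default_rng(seed)` drives all volumes in a fixed key order).

What the phantom does *not* emulate: k-space acquisition and zero-filling
artifacts, partial-volume blur at region boundaries, coil inhomogeneity,
motion, susceptibility physics around iron particles, and between-animal
anatomical variability. Passing tests therefore demonstrate correctness of
the quantification arithmetic under the stated signal models, not robustness
to those real-data effects.

## Histology synthesis and quantification

Brightfield images obey Beer–Lambert absorption:
`I_c = I0_c · 10^(−Σ_s density_s · v_{s,c})` with unit stain absorption
vectors v (defaults: the published Ruifrok–Johnston H-DAB pair,
overridable). Vacuoles are ellipses rendered at background white (zero stain
density), matching their appearance as unstained holes.

Quantification inverts that model: OD = −log₁₀(I/I₀) (intensities clipped to
[10⁻¹²·I₀, I₀] before the log), densities solved per pixel from the
completed 3×3 stain matrix (third row = normalized cross product of the two
stain vectors), negative densities clipped to zero and counted. On
noise-free synthetic images the round trip is exact to ~10⁻¹⁵ OD, well
inside the 10⁻⁶ tolerance asserted. Stain matrices with condition number
above 10⁶ are rejected as collinear.

Mean DAB OD uses a standard circle whose diameter is an explicit parameter
in pixels (the original workflow's "500 units" at ×10 magnification is
ambiguous, so nothing is hard-coded), averaged unweighted across sections.
Vacuolation scoring: optional rolling-ball background subtraction →
binarize (Otsu by default; fixed threshold for deterministic tests; a
constant image falls back with a warning) → score = ROI area × mean binary,
which equals the vacuole pixel count inside the ROI by construction.

## Cohorts and statistics

`generate_cohort` draws per-animal ROI measurements from Gaussian cells
(group × age), five ages 40–120 d and n = 4–5 per cell as in the study
design; the source prints no per-animal variances, so cell SDs are free
parameters (default 1.0, i.e. effects are specified directly as Cohen's d).
The statistics layer implements the Holm step-down adjustment (verified
against both a literal-rule oracle and statsmodels), pooled-SD Cohen's d
(Glass's Δ selectable), Pearson r, and the Fisher r-to-z comparison
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)). The omnibus ANOVA is an OLS
two-way (group × age, categorical, with interaction) via statsmodels.

Post hoc tests are Welch by default — the safer choice on real data with
unequal cell variances. Note that at n = 5 the Welch approximation is
tail-conservative (per-test size ≈ 0.013 at nominal 0.0167), so exact
family-wise calibration checks use the pooled Student variant, which is
exact under equal-variance Gaussian nulls; the family-wise error of the
Holm procedure then sits at 1 − (1 − α/m)^m ≈ 0.049 for m = 3, α = 0.05.

## Detection and ROI conventions

* Hypointensity rule: threshold = fraction × mean over *all* mask voxels
  (no iterative re-estimation); strict `<`; components labelled at
  connectivity 26 by default (6/18 available and recorded); size > 20
  excluded (`≥` selectable); excluded voxels stay in the denominator.
* Voxel indices are 0-based; world mm coordinates via the NIfTI affine
  `diag(voxel_size)`, so voxel (i,j,k) sits at (i·dx, j·dy, k·dz) mm.
* Circular/spherical ROIs include a voxel iff its centre lies in the closed
  disk/ball, with a 10⁻¹² relative slack on r² so centres exactly on the
  boundary are included regardless of floating-point rounding direction;
  the phantom's nucleus masks use the same rule so ROI recovery is exact.
* Printed ROI sizes are interpreted as diameters in mm by default; an
  area-in-mm² reading (diameter = 2√(A/π)) is selectable
  (`diameter_is_area`), since the two interpretations differ by only ~3%
  in diameter but both appear in the literature.
* The control-region mean is pooled across slices; ADC fits flag negative
  diffusivities invalid rather than clipping (clipping selectable); invalid
  voxels are excluded from ROI means and counted, never imputed.

## Numerical and scaling choices

* ADC fitting is closed-form OLS on (b, ln S) with intercept, vectorized;
  exact for noise-free mono-exponentials (< 10⁻¹² mm²/s error). Under
  Rician noise at SNR 20 (b=0 signal) the voxelwise trace RMSE at
  D = 0.7×10⁻³ mm²/s is ≈ 11% of D — the delta-method floor for this
  three-point b-scheme; a signal-weighted fit would reach ≈ 10.3%.
* Scan-duration arithmetic is TR × phase encodes × averages × repeats; the
  zero-filled resolution is FOV / reconstructed matrix (22.5 mm / 256 =
  87.9 µm ≈ 88 µm isotropic).
* Test problem sizes: phantoms of ~5×10⁴ tissue voxels, oracle comparisons
  on 32³ volumes, 10⁴ replicates for the family-wise-error calibration and
  10³ for effect-size consistency — large enough for the stated tolerances
  at interactive runtimes.
* The pipeline writes plain files plus a manifest (config hash, seed,
  stage inventory); identical config + seed reproduce byte-identical CSVs.

## Known limitations

* No registration: all volumes are assumed voxel-aligned (single-session
  acquisition); misalignment handling is out of scope.
* No diffusion-tensor or multi-compartment models; the trace is the
  unweighted mean of three orthogonal directional fits.
* The hypointensity detector operates on whatever grid it is given; voxel
  size only enters through reporting.
* Otsu binarization on low-contrast vacuole images is sensitive to the
  intensity histogram; the fixed-threshold mode is recommended when the
  white level is known.
* Cohort simulation is cross-sectional with independent Gaussian cells; no
  repeated-measures or litter structure.
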