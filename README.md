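# sod1mri

Quantification stack for multimodal MRI and histology of brainstem
motor-nucleus degeneration in the SOD1-G93A mouse model of amyotrophic
lateral sclerosis (ALS), built for imaging scientists who need every stage of
the analysis to be verifiable without animal data.

The package re-implements, as a tested library plus CLI, the measurements of
a longitudinal 7-T mouse study: T2-weighted hyperintensity in the trigeminal
(V), facial (VII) and hypoglossal (XII) motor nuclei, apparent diffusion
coefficient (ADC) and magnetization transfer ratio (MTR) maps,
gadolinium-enhancement maps for blood–brain-barrier integrity, detection of
iron-oxide microparticle (MPIO) hypointensities on T2*-weighted volumes, DAB
immunostain densitometry and H&E vacuolation scoring, and the comparison
statistics that tie them together. Every stage is driven by a synthetic
phantom generator that emits ground truth alongside the data, so each
quantity can be checked exactly.

## The measurements

* **ADC trace.** Per gradient direction the signal follows
  S(b) = S₀·exp(−b·D); D is −slope of the OLS line through (b, ln S) at
  b ∈ {125, 500, 1000} s/mm², and the trace is the mean of the three
  orthogonal directional maps (mm²/s).
* **MTR.** (S_off − S_on)/S_off — fractional signal lost to an off-resonance
  saturation pulse.
* **Gd enhancement.** (S_post − S_pre)/S_pre after contrast injection.
* **ROI contrast.** (mean ROI − mean control)/mean control, with a control
  region inside the brainstem but outside the nuclei; the sign is inverted
  for ADC/MTR so all modalities plot in the same direction.
* **MPIO hypointensities.** Voxels < 65% of the mean signal over the tissue
  mask, grouped into connected components; components larger than 20 voxels
  are excluded (sinuses etc.); burden = % retained hypointense voxels.
* **DAB optical density.** OD = −log₁₀(I/I₀) per channel, unmixed into
  hematoxylin/DAB densities by Ruifrok–Johnston colour deconvolution; mean
  DAB density in a standard circle, averaged over sections.
* **Vacuolation.** Background-subtract, binarize (vacuoles are bright
  holes), then ROI area × mean binary = vacuole pixel count.
* **Statistics.** ANOVA with Holm–Bonferroni-corrected post hoc t-tests,
  pooled-SD Cohen's d, Pearson r, and Fisher's z′ = atanh(r) comparison of
  two correlations: z = (z₁′ − z₂′)/√(1/(n₁−3) + 1/(n₂−3)).

## Worked example

```python
import sod1mri as s

# end-stage phantom: 15-fold T2 hyperintensity in nucleus VII,
# one detectable MPIO cluster (8 voxels) and one oversized one (30 voxels)
spec = s.PhantomSpec(mpio_clusters=(
    s.ClusterSpec(center=(2.4, 2.4, 2.4), size=8, depth=0.4),
    s.ClusterSpec(center=(4.0, 2.4, 2.4), size=30, depth=0.4),
))
vs, truth = s.generate_mri_phantom(spec)

ctl = s.RoiDefinition("control", center=(3.2, 3.4, 2.4), diameter=1.0)
nuc = next(n for n in spec.nuclei if n.label == "VII")
roi = s.RoiDefinition("VII", nuc.center, nuc.diameter, control_link="control")
m = s.measure_roi(vs["t2"], roi, ctl, spec.voxel_size, modality="t2")
print(f"T2 contrast in VII: {m.contrast:.1f}")

res = s.detect_hypointensities(vs["t2star"], truth.tissue_mask)
print(f"clusters retained: {len(res.clusters_retained)}, "
      f"excluded: {len(res.clusters_excluded)}, "
      f"percent hypointense: {res.percent_hypointense:.4f}")
```

prints

```
T2 contrast in VII: 14.0
clusters retained: 1, excluded: 1, percent hypointense: 0.0160
```

A 15-fold hyperintense nucleus has normalized contrast 15 − 1 = 14 against
the control region, recovered exactly on the noise-free phantom. The
detector keeps the 8-voxel cluster (≤ 20 voxels, 40% depth) and excludes the
30-voxel one; 8 of 50 069 mask voxels ≈ 0.016%.

The same flow runs from the shell:

```bash
sod1mri run --out run_dir --seed 1        # full pipeline + manifest
sod1mri phantom mri --seed 1 --out ph/    # just the phantom (NIfTI + truth)
sod1mri maps --manifest ph/manifest.json --out maps/
```

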