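# gwseg — atlas-free grey-white interface segmentation for infant T2w MRI

Reconstructing the inner cortical surface (the boundary between the cortical
ribbon and the underlying white matter) is notoriously hard in the first
post-natal months: unmyelinated white matter inverts and weakens the usual
tissue contrast, maturation changes intensities regionally, and the folded
ribbon is only a few voxels thick at ~1 mm resolution. `gwseg` implements an
atlas-free pipeline for T2-weighted volumes aimed at exactly this regime. It
is intended for researchers working on developing-brain morphometry who need
a segmentation that does not depend on age-specific templates.

## Method

The pipeline has two stages.

**1. Feature field.** Three local detectors are combined into a signed scalar
field `f` with white matter positive and cortex negative:

- `TH^GM`: dark top hats, `Closing(I; e(s, θ)) − I`, with square structuring
  elements of side s ∈ {2, 4} mm in 9 plane orientations (3 axis-aligned + 6
  bisecting); the maximum over orientations responds to the thin dark cortical
  ribbon regardless of its local orientation.
- `TH^WM`: bright top hats, `I − Opening(I; e(s, θ))`, s ∈ {4, 7, 14} mm, for
  thin bright white-matter structure (gyral cores, fingers).
- `MC^WM`: the rectified negative mean curvature of isointensity surfaces,
  `max(0, −H)` with `H = ½ ∇·(∇I/|∇I|)`; its maxima trace the gyral ridge
  lines of white matter, a geometric cue that survives contrast loss.

After normalization (sigmoidal for the top hats, linear for the curvature):

```
f = (w_wm·TH^WM + w_mc·MC^WM − w_gm·TH^GM) / (w_gm + w_wm + w_mc)
```

with per-volume thresholds `F^WM = 0.12·max f` and `F^GM = 0.08·min f`
bounding the weak-contrast band.

**2. Coupled homotopic deformation.** Two digital surfaces are initialised on
each side of the interface: the inner region from a threshold of the field
(the white-matter body) and the outer region from the brain bounding box.
Both fronts grow by single-voxel ICM steps that must decrease the energy
`U = U_D + U_R`, where `ΔU = −σf + β(26 − 2n)` (σ = +1 inner / −1 outer,
n = 26-neighbours already in the region — an Ising regularization). A first
round moves each front through confident territory only (`f > F^WM` inner,
`f < F^GM` outer). A second round drives convergence with a *potential to
move*: every candidate carries a potential P₀ decremented by `P₀·(S/S_high)`
per sweep, with the speed S read from per-surface tables of (f, n) —
`S_high` in confident territory, interpolated in the band, and a strictly
positive `S_verylow` for the outer surface even against the energy, so it
crosses residual CSF. Every outer move must pass a simple-point (homotopy)
test, so the outer surface keeps its spherical topology throughout; the
fronts freeze where they meet, and that meeting set is the grey-white
interface.

A synthetic phantom generator (folded-sheet geometry with analytic ground
truth, T2w intensity ordering, bias field, noise, and an optional regional
contrast-loss box mimicking maturation) plus Dice / surface-distance /
landmark-distribution evaluation tools make the whole pipeline testable
without any clinical data.

## Worked example

```python
from gwseg import make_phantom, phantom_suite, segment_white_matter
from gwseg import dice_coefficient, surface_distance_map
from gwseg.surface_model import DigitalRegion

truth = make_phantom(phantom_suite()[0])          # high-contrast preset, 96³
result = segment_white_matter(truth.volume, truth.brain_mask)

dice = dice_coefficient(result.wm_mask, truth.wm_mask)
err = surface_distance_map(
    result.interface,
    DigitalRegion(truth.inner_interface, spacing=truth.spec.spacing),
)
print(f"Dice {dice:.4f}  interface error {err.mean:.3f} mm  "
      f"outer chi {result.state.outer_complement_euler()}")
```

prints

```
Dice 0.9798  interface error 0.419 mm  outer chi 2
```

i.e. the recovered white matter overlaps the ground truth at Dice 0.98, the
reconstructed interface sits within half a voxel of the true one on average,
and the outer surface ended the deformation still sphere-equivalent (Euler
characteristic 2), as the homotopy constraint guarantees.

The same run from the shell:

```
gwseg phantom --out ph --preset young
gwseg segment --t2 ph/t2.nii.gz --mask ph/brain_mask.nii.gz --out wm.nii.gz
gwseg evaluate --auto wm.nii.gz --manual ph/wm_truth.nii.gz \
               --landmarks ph/landmarks.tsv --report report.json
```

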