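# Methods

This note documents the model implemented by `gwseg`, the defaults and why
they are what they are, what the synthetic phantoms do and do not emulate,
and the numerical decisions made where the design was genuinely open.

## Problem and model

The target structure is the grey-white interface of the infant brain in
T2-weighted MRI at ~1 mm isotropic resolution. In the first post-natal
months, unmyelinated white matter is *brighter* than cortex and CSF is
brightest; the WM-GM contrast is weak and decreases further with maturation,
earliest in primary cortices. The method therefore avoids atlases and pure
intensity classification, and instead relies on two priors of the subject's
own anatomy: (i) the cortical ribbon is a thin dark sheet of fairly steady
thickness (2–4 mm), and (ii) white matter forms bright ridge lines (gyral
crests) at every maturational stage.

### Feature field

- **Directional top hats.** Grey-scale closing (dark variant) or opening
  (bright variant) residues with flat square structuring elements rasterized
  in 9 plane orientations — the 3 coordinate planes and the 6 planes through
  one axis and a face diagonal. Taking the maximum over orientations makes
  the detector approximately rotation covariant (a flat slab rotated by 45°
  changes the mean ribbon response by under 25%, which the tests check).
  Element sides: 2 and 4 mm for the ribbon (matching cortical thickness), 4,
  7 and 14 mm for bright WM structure; per detector the per-size maxima are
  averaged with uniform weights. Sizes in mm are converted to voxels by
  sampling the square at half the voxel pitch and rounding (minimum one
  voxel). Boundary handling is replicate padding; because clamped-index
  closing/opening is not an adjunction at the border, the residues are
  clipped at zero there (the top hat is nonnegative by contract).
- **Isointensity mean curvature.** After a 1 mm Gaussian pre-smoothing, the
  mean curvature H of the implicit level set through each voxel is evaluated
  from first and second derivatives, with the normal along +∇I. Bright WM
  crests then have H < 0 and the ridge response is MC^WM = max(0, −H),
  clipped at the 99.5th percentile (the crest itself is a singularity) and
  zeroed where |∇I| falls below 10⁻³ of the masked intensity range per mm.
- **Normalization.** Top-hat responses inside a brain mask are bimodal: a
  hump of small noise residues plus a structural tail. The logistic
  normalization is therefore centred at the Otsu threshold of the positive
  responses with slope = ¼ of the separation of the two class means: the
  noise hump compresses toward 0 and the tail saturates toward 1. (Centring
  at the median of positive responses — a plausible alternative — puts the
  sigmoid midpoint on the noise floor and turns featureless white matter
  into amplified noise.) The curvature map is normalized linearly.
- **Denoising of the normalized maps.** The two top-hat maps pass through a
  3-voxel median filter: edge-preserving, so the sharp ribbon transitions do
  not move (a Gaussian here drags the zero crossing of the combined field
  about a voxel into the white matter). The curvature map instead is pooled
  with a 1 mm Gaussian: the rectified response is speckle by nature (it
  rides on noise isophotes in homogeneous tissue) and pooling turns it into
  a smooth white-matter-interior prior; since the cortex response is ≈ 0,
  bleed across the interface is negligible.
- **Combination.** Weighted average with weights (w_gm, w_wm, w_mc) =
  (1, 1, 1.5), clipped to [−1, 1], zero outside the mask. The curvature term
  gets the extra weight because it is the only detector carrying signal deep
  inside homogeneous white matter, where the noise residues of the two
  opposing top hats cancel on average. Thresholds: F^WM = 12% of the highest
  and F^GM = 8% of the lowest masked feature value.

### Coupled homotopic deformation

Two voxel regions grow toward each other across f; their exposed facets are
the two surfaces.

- **Energy.** ΔU = −σf + β(26 − 2n) per candidate addition (σ = +1 inner,
  −1 outer; n = 26-neighbours already in that region). β defaults to 0.005
  of the feature magnitude so that the full Ising range ±26β is comparable
  to the weak-contrast band [F^GM, F^WM]: regularization arbitrates
  weak-evidence moves but never overrides confident feature evidence. The
  inner surface moves only on strict energy decrease; the outer surface
  falls back to the S_verylow creep when ΔU ≥ 0, which is what lets it cross
  residual CSF and guarantees termination.
- **Initialisation.** Outer = complement of the brain bounding box (a
  topological sphere). Inner = largest 26-connected component of the
  despeckled field at threshold 0+ (median filter, size 3; inclusive
  threshold so that regions where no detector fires at all — deep inside a
  homogeneous WM body — stay on the white-matter side), with cavities
  filled so the initial surface is closed. This makes the initial inner
  region a rough fit of the final interface that hands the front the
  white-matter bulk, whose interior carries no local feature signal; the
  deformation then only negotiates the band near the boundary. An explicit
  surface-area target is supported (threshold found by bisection to within
  10% of the requested boundary facet count).
- **Speeds.** Round 2 uses per-surface speed tables. Inner: S_high above
  F^WM; zero below F^GM unless n > N (then S_low); in the band, speed
  interpolates linearly from S_low (at F^GM) to S_high (at F^WM), gated by a
  neighbour threshold N_I(f) that equals N_I_min on the favourable half
  (f ≥ 0) and ramps to N at F^GM — extra support is demanded only where the
  evidence actually opposes the move. Outer: S_high below F^GM; S_verylow
  above F^WM (S_low when n > N); in the band, S_verylow on the non-GM half
  (f ≥ 0, where its only sanctioned role is the residual-CSF creep) rising
  to S_high at F^GM. Defaults S_high/S_low/S_verylow = 1/0.25/0.05, N = 22,
  N_I_min = N_O_min = 9, P₀ = 1.
- **Scheduler.** Each candidate's potential decreases by P₀·(S/S_high) per
  sweep and triggers at zero — one sweep at S_high, round(S_high/S) sweeps
  at lower speeds; the potential is reset when the location propagates.
  (Resetting it whenever a neighbouring voxel moves was considered and
  rejected: any candidate slower than S_high next to an active front then
  never accumulates decrements and the front livelocks.) Sweeps visit voxels
  in fixed lexicographic order, so runs are bitwise deterministic.
- **Topology.** Every outer addition must be a simple point. The test counts
  topological numbers for the (6, 26) connectivity pair: one 6-connected
  component of region neighbours in the geodesic 18-neighbourhood (touching
  a face neighbour) and one 26-connected component of background neighbours.
  This pair — rather than (26, 6) — is the one consistent with the
  cubical-complex boundary realization used to verify topology: under it,
  random homotopic growth keeps the complement's Euler characteristic at
  exactly 2 (16,000/16,000 additions in the stress test), whereas under
  (26, 6) the cubical realization glues diagonal contacts of the complement
  and χ drifts. The swapped pair remains available.
- **Termination and finalization.** Candidates facing both fronts freeze as
  interface. The loop ends when nothing changes for a full quiet period
  (long enough for the slowest speed to trigger). Leftover pockets reached
  by only one front were never contested and are absorbed by the enclosing
  region; interface voxels join the white matter where f ≥ 0. The returned
  interface is the exposed boundary of the final WM mask.

## Synthetic phantoms

The generator builds a folded-sheet geometry: the interface is the height
field z = z₀ + A·sin(2πx/λ)·sin(2πy/λ) with white matter below, inset from
the grid border so a cortical ribbon of constant thickness (Euclidean
distance ≤ t) wraps it completely, CSF outside, and the brain mask one voxel
beyond the tissue (leaving a residual CSF rim for the outer surface to
cross). Intensities follow the infant-T2w ordering (defaults WM 160, GM 90,
CSF 220), with a smooth multiplicative bias (sum of three broad Gaussians,
default ±15%) and additive Gaussian noise (default sd 8, i.e. WM-GM CNR ≈ 9
at full contrast). Landmarks sample the sulcal-fundus analog (vertical
sheets over the trough lines, analytic normals, 2 mm spacing).

The fixed three-phantom suite: **young** (full contrast), **old** (same
geometry with the WM-GM difference reduced to 20% inside a box over part of
the folded band — maturation makes central-region contrast nearly vanish,
and it strikes the cortex of primary areas, not deep WM), and **narrow**
(fold wavelength 6 mm ≈ 2.4× the 2.5 mm ribbon, stressing partial volume in
narrow gyri).

What the phantoms do *not* emulate: Rician noise statistics, genuine
partial-volume mixing beyond grid sampling, deep grey nuclei, ventricles,
anatomically realistic folding, or inter-subject variability. Passing the
suite therefore demonstrates the mechanics of the method — detector
correctness, topology preservation, convergence, the directional effect of
contrast loss — not clinical accuracy; the published real-data figures
(Dice ≈ 0.87, reconstruction error ≈ 0.4 mm against manual segmentations)
are not reproducible without the original infant scans, and phantom scores
are expected to be higher than real-data scores.

## Degenerate inputs and numerical details

- Strictly-ΔU ICM on an exactly constant field freezes at 45° fronts (a
  candidate on such a front has n = 13, ΔU = 0); the inclusive
  initialisation threshold and the finalization rule make the noise-free
  flat-slab phantom converge exactly nonetheless.
- The potential trigger uses a 10⁻⁹ tolerance so k decrements of P₀/k
  trigger in exactly k sweeps despite float rounding.
- Hysteresis CSF filtering treats low = high as plain thresholding; the
  removal is 26-connected.
- mm → voxel conversion is round(size/spacing), minimum 1 voxel; the engine
  treats voxels isotropically and warns when spacing anisotropy exceeds 1.5×.
- Problem sizes: the suite phantoms are 96³ voxels at 1 mm; unit tests use
  48³ companions with identical tissue parameters. A full 96³ segmentation
  runs in well under a minute on one CPU core (feature field ~10 s,
  deformation ~100–300 sweeps).

## Known limitations

- The interface is voxelized; no sub-voxel positioning or level-set
  refinement is attempted.
- The homotopy constraint applies to the outer surface only (the inner
  region may change topology), and the simple-point test is local, so rare
  global-topology leaks of purely local tests are accepted — the suite runs
  never exhibit one.
- Speeds, gates and combination weights stand in for quantities whose exact
  published forms are not recoverable; all are exposed in the run
  configuration and their defaults are justified above.
- Only the inner cortical (grey-white) surface is extracted; the pial
  surface, multispectral input and longitudinal modelling are out of scope.
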