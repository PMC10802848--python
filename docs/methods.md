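# Methods

## Model and assumptions

The algorithm quantifies DWI/FLAIR mismatch as the fraction of a DWI-defined
ischemic lesion that is already hyperintense on FLAIR. It assumes (i) the
DWI mask and FLAIR volume are related by their NIfTI header affines (no
intensity-based cross-modal registration is attempted); (ii) healthy brains
are approximately left-right symmetric, so the mirrored hemisphere provides
a per-voxel reference intensity once residual head tilt is removed by rigid
registration; (iii) normal-appearing parenchyma in a slice summarizes the
local intensity distribution well enough that slice mean/SD thresholds are
meaningful. The parenchyma mask (brain without ventricles/CSF) is an input;
producing it is out of scope.

All volumes are reoriented to RAS+ on load, so axis 0 is the left-right
world axis and mirroring is an index flip on axis 0. Voxel indices are
0-based, voxel centers map through the affine. Masks are resampled
nearest-neighbor, intensity images trilinearly.

## Segmentation criteria

A ROI voxel with intensity I, contralateral sample C, in slice s:

- criterion 1: C valid, C > ε, I/C > `ratio_threshold` (default 1.15,
  strictly above), and I ≥ μₛ + `sd_mult_low`·σₛ (default 0.25, inclusive);
- criterion 2: I > μₛ + `sd_mult_high`·σₛ (default 1.25, strict).

Comparison strictness follows the wording of the rules the defaults come
from ("above", "at least as bright", "brighter than"). The ε guard
(10⁻⁶ × volume max) disables criterion 1 where the contralateral sample is
near zero rather than produce unbounded ratios; out-of-field contralateral
samples likewise disable criterion 1 only. σₛ uses the population
definition; at slice scale the sample/population distinction is negligible
but a convention must be fixed. Slices with fewer than `min_slice_voxels`
(default 50) reference voxels fall back to whole-volume statistics.
No morphological post-processing is applied. The `contralateral_only`
ablation segments on the ratio alone.

The criteria are scale-equivariant: multiplying all intensities by c > 0
scales I, C, μₛ and σₛ alike, leaving the segmentation unchanged.

## Mirror registration

The mirrored volume is registered to the original by minimizing the mean
absolute intensity difference over brain-mask voxels (restricting to brain
avoids background dominance; the choice of cost region was open and
brain-only is the standard one). The optimizer is bounded Powell over
(tx, ty, tz) in mm and three Euler angles, initialized at identity, run on
a coarse (≤6000 voxels) then fine (≤40000) point subset; if the final cost
exceeds the identity cost the identity is returned. The moving volume is
sampled with a cubic B-spline (pre-filtered once per registration):
trilinear sampling leaves edge-aliasing noise in the cost that is
comparable to the cost differences a ~1° rotation produces, and was
observed to bias the optimum by about a degree on phantoms.

The transform convention is world-mm, rotation about the volume center,
extrinsic x-y-z Euler angles; transforms serialize to a plain-text
key-value file for audit.

## Exclusion rules

- Empty projected ROI → excluded (`empty_dwi_roi`); mirrors cohort
  exclusions where upstream DWI segmentation missed the stroke.
- ROI ∩ mirrored(ROI) / |ROI| strictly greater than 0.20
  (`--overlap-threshold`) → excluded (`mirror_overlap`): the contralateral
  reference partly comes from the lesion itself. The measures are still
  reported but flagged unreliable. Exclusion is a successful run with a
  flagged result, not an error.

## Phantoms

Phantoms exist to make every code path testable with analytic truth, not to
simulate MRI physics. The anatomy is an ellipsoidal brain (semi-axes
0.40/0.46/0.38 of the grid, mirror-symmetric about the grid midplane) with
a thin hypo-intense ventricle pair and four mirror-symmetric internal
structures (a deep-nuclei pair at 80% of parenchymal intensity, a bright
anterior band at 115%, a dark posterior-inferior region at 85%). The
structures are not cosmetic: a bare ellipsoid with centered ventricles is
nearly invariant under in-plane rotation and under front-back/up-down
flips, which makes mirror registration ill-conditioned and creates
competing optima; the structures break those near-symmetries the way real
anatomy does.

Tissue interfaces carry a quintic-smoothstep intensity ramp ~2.4 voxels
wide emulating partial-volume edges, while plateaus stay *exactly*
constant. The C² profile matters: a kinked (piecewise-linear) ramp causes
systematic spline-interpolation ringing that biased registration recovery
by ~1°. Interior constancy is what makes exact-recovery tests possible:
default intensities (background 20, parenchyma 100, ventricles 40) are
chosen so slice means are computed exactly in floating point.

The lesion is an ellipsoid (default ~500 voxels at 3 mm isotropic, i.e.
~13 mL, a mid-sized stroke) placed laterally in one hemisphere. A
`lesion_fraction_hyper` sub-region — a deterministic anterior-to-posterior
split, so the fraction is hit to voxel-rounding accuracy — is painted at
`lesion_contralateral_ratio` (default 1.5) times the intensity of its
anatomical twin, read off the symmetric pre-lesion base image. With a
contralateral confounder present, the twin is still the pre-confounder
value; otherwise the confounder would raise the lesion intensity and stop
being a confounder. Midline-crossing lesions solve the ellipsoid-cap
equation for the center offset that yields the requested crossing
fraction. Head misalignment (whole-head rigid shift/rotation) is applied by
evaluating all geometry on rigidly pulled-back coordinates, so the
misaligned phantom has crisp analytic edges rather than resampling-smoothed
ones, and the registration ground truth is the closed form
T·Mirror·T⁻¹·Mirror. (A "one-hemisphere" perturbation was considered and
rejected: it creates a non-physical seam at the midline, whereas whole-head
misalignment is what head tilt actually produces and has a closed-form
expected transform.) Noise is additive Gaussian; Rician noise is out of
scope as the criteria depend only on relative intensities. Default
`noise_sd` is 0 so the generator's defaults are the exact-recovery
conditions; noisy tests set it explicitly (recovery DICE ≥ 0.95 at 5% of
parenchymal intensity).

Cohorts sample "match" cases (FLAIR-visible fraction 0.92–1.0) and
"mismatch" cases (0–0.08) with jittered lesion side, position and size;
lesion placement is rejection-sampled against ventricles, structures and
the brain edge. The truth table codes `flair_visible` = 1 for match cases,
so the mismatch ratio correlates positively with the label.

What phantoms do **not** emulate: gyral texture, bias fields, partial
anatomy asymmetries, real WMH morphology, DWI physics. Passing tests
demonstrate the pipeline's internal correctness (criteria logic,
registration recovery, exclusion rules, statistics), not clinical accuracy.

## Numerical choices

- Nearest-neighbor mask resampling never creates values other than 0/1 and
  is the identity on identical grids.
- Registration tolerances: Powell `xtol` 1e-4, `ftol` 1e-6, ≤200 iterations
  per level; bounds ±30 mm, ±15°.
- Problem sizes: default phantom 64×64×48 at 3 mm; 10 phantoms for the
  sweep; 20 for the cohort correlation; criteria-oracle checks on 100
  random 24³–32³ volumes. These sizes make the whole suite run in minutes
  while leaving each property's failure modes observable.
- DICE of two empty masks is defined as 1.0 (never arises clinically;
  needed for the fully-mismatched phantom where truth and segmentation are
  both empty).
- The intensity measure uses global (not per-slice) means and excludes the
  ROI from the denominator; both choices were open and the simplest
  reading was taken.
- The point-biserial coefficient delegates to `scipy.stats.pointbiserialr`
  (it *is* the Pearson correlation against 0/1 labels); tests cross-check
  against an independent Pearson + t-distribution computation.

## Known limitations

- Header-affine DWI→FLAIR alignment inherits any header error; there is no
  intensity-based cross-modal fallback.
- The slice axis defaults to canonical axis 2 (axial); the true acquisition
  axis is not reliably recoverable from NIfTI. Override with `--slice-axis`.
- The mirror plane is the grid midplane; registration absorbs moderate
  midline offset (phantom tests cover ~2 voxels / ~2°), but grossly rotated
  acquisitions should be reoriented first.
- On a perfectly symmetric brain the registration optimum is degenerate
  along the mirror normal only in the absence of asymmetric structure;
  real brains (and the phantoms) provide enough asymmetry in practice.
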