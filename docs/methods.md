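# Methods

## Model and procedure

STIR suppresses fat signal, so inflammatory fluid in bone marrow appears
hyper-intense against the low, roughly homogeneous signal of normal marrow.
The quantification model treats normal-marrow intensity inside one image
set as approximately Gaussian with mean *m* and SD *s*, estimated from a
user-placed reference ROI in visibly healthy marrow, and declares a marrow
voxel lesional when its intensity exceeds *T = m + k·s* (strict
inequality; a voxel exactly at *T* is normal). Supra-threshold voxels are
grouped into connected components and components below 10 voxels are
removed: under the Gaussian model the expected number of false-positive
voxels in a typical segmented marrow volume at *k* ≈ 4 is below one, and
the chance that noise voxels form a 10-voxel connected cluster is
negligible, so the size filter converts a per-voxel error rate into an
essentially zero per-object error rate. Each surviving component is
reported as one lesion.

Outputs per image set: `volume_hyper` (surviving voxel count × voxel
volume), object count, and the pooled per-voxel relative intensity
`S_RelHyper = (S_hyper − m)/m` summarised by mean, median, 75th and 90th
percentile. Pooling is over voxels, not over lesions, so large lesions
weigh proportionally to their size.

Assumptions worth keeping in mind: the ROI truly samples normal marrow
(an ROI contaminated by edema inflates *m* and *s* and masks lesions); the
intensity scale is spatially uniform (see bias fields below); and masks
live on the image grid — no resampling is performed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 4.15 (spine), 2.64 (SI) | SD multiplier; ROC-calibrated per anatomy. Lower `k` trades specificity for sensitivity. |
| `min_size` | 10 voxels | smallest component kept as a lesion |
| `connectivity` | 26 | 3D adjacency (6/18/26); 4/8 run per-slice 2D labelling for slice-level analyses |
| `include_gap` | false | whether a voxel's volume credits the inter-slice gap (thickness × (1 + gap fraction)). Off by default: signal is only sampled within the slice. |
| ROI size | ≥ 200 voxels | smaller ROIs only warn, but the *m*, *s* estimates get noisy |
| `n_bins` | 256 | histogram-matching quantile resolution |

The SD uses the *n − 1* denominator (sample SD of a measured region).
Percentiles interpolate linearly between order statistics at rank
*p·(n−1)+1* (numpy's default rule), a stated convention so results are
bit-reproducible across implementations.

## Intensity normalization

MR intensities are in arbitrary units, so cross-session comparability
requires normalization. `match_histogram` is a binned quantile mapping:
each volume is histogrammed over its own min–max span (equivalent to
min–max scaling both volumes onto a shared grid) at `n_bins` equal-width
bins; a voxel is pushed through the piecewise-linear image CDF and the
piecewise-linear inverse reference CDF. The map is monotone
non-decreasing, so voxel ranks — and therefore which voxels end up above a
rank-equivalent threshold — are invariant to any strictly monotone
re-scaling of the input. A constant image maps to the reference median; a
constant reference with a varying image has no defined target and raises.

Note the thresholding pipeline itself is scale-equivariant (threshold and
ROI statistics come from the same image), so normalization matters mainly
when one fixed reference image or pooled intensity statistics are used
across sets. `synthetic_reference(anatomy)` provides a deterministic
synthetic stand-in reference volume (a fixed-seed lesion-free noise
phantom) for users without a suitable reference acquisition; a real
scanner reference is preferable. Normalizing to muscle-tissue signal is
sometimes advocated for this problem; it is deliberately not implemented
here, as there is no agreed formula for it in this pipeline.

## Calibration

`sweep_k` runs the full pipeline per case over a strictly increasing `k`
grid; a case is test-positive when at least one lesion survives (an
alternative total-volume rule is available). Because supra-threshold sets
are nested in `k`, sensitivity is non-increasing and specificity
non-decreasing along the grid, so the points form a proper ROC staircase.
AUC is the trapezoidal area over (1 − specificity, sensitivity) after
appending the (0, 0) and (1, 1) corners; tied false-positive-rate points
are ordered by sensitivity so they contribute vertical segments, which
makes the trapezoid area equal the tie-aware Mann–Whitney statistic
whenever the grid spans every case's detection transition (the
permutation-null test in the suite verifies the mean over all labellings
is exactly 0.5). The operating point maximizes Youden's
J = sensitivity + specificity − 1, ties broken toward larger `k` (higher
specificity). The default grid is 0.25–6.0 in 0.05 steps, spanning both
anatomy presets.

## Agreement statistics

`confusion` cross-tabulates per-unit reference vs test positivity
(reference positive ⇔ score > 0). `confusion_from_counts` reconstructs
the 2×2 table when only aggregates are published — total units, reference
positives, test positives, and agreed negatives — and raises on
inconsistent counts. Sensitivity/specificity are `None`, not 0, when a
margin is empty. Spearman's rho is Pearson on mid-ranks (scipy backend;
an explicit mid-rank oracle cross-checks it in the tests).
`aggregate_cohort` extends a lesion-positive-subset mean to an all-set
mean by counting the remaining sets as exact zeros — the convention used
when cohort summaries include sets without lesions; intensity summaries of
empty sets are flagged absent instead of zero so they are *excluded* from
such means. Linear-mixed-model analysis of the per-set table is out of
scope; `tidy_results_table` exports the metrics-with-scores table that any
external LMM tool can consume.

## The phantom generator

`generate_phantom` emulates what the pipeline is sensitive to:

- a rectangular "bone" region (default: central half in-plane, all slices
  of a 64×64×12 grid at 1×1×4 mm, 10% slice gap) at marrow intensity
  μ = 100 with noise σ = 10;
- surrounding soft tissue at 40 ± 8;
- ellipsoidal lesions with additive contrast Δ·σ over the (bias-scaled)
  marrow baseline — ground truth is the geometric ellipsoid mask, so
  volume-recovery tolerances must absorb the per-voxel detection
  probability Φ(Δ − k), not just noise in the detected set;
- an optional multiplicative Gaussian-bump bias field
  1 + β·exp(−d²/2λ²) anchored at a bone-region corner, mimicking
  coil-proximity shading: for (1 + β)·μ > T it produces false-positive
  objects in lesion-free marrow, which disappear when the reference ROI is
  placed inside the high-bias region (the threshold adapts) — the known
  failure mode of global thresholds on off-centre anatomy;
- Gaussian noise by default (analytically tractable tails); Rician
  (magnitude of two Gaussian channels) available, since magnitude MR noise
  is Rician — at the SNR of these phantoms (≥ 4) the two are nearly
  indistinguishable.

The reference ROI is auto-placed as an in-plane disk of radius 8.5 voxels
(≈ 225 voxels, above the 200-voxel floor) at the bone centre in the first
lesion-free slice, erroring if no such slice exists; explicit placement
overrides. Everything is driven by one `numpy` Generator seed;
regeneration is bit-identical.

What the phantom does **not** emulate: vertebral/joint anatomy,
partial-volume edges, fat-suppression failures, motion, multi-coil
composite bias, or pathologies other than bright edema. Passing the
phantom suites therefore shows the *algorithmic* chain is correct
(thresholds, components, volumes, calibration), not that the method's
clinical accuracy on patient data is reproduced — the published
patient-cohort accuracies depend on the original MRI data and reader
scores, and only their count-determined summaries are recomputed here.

## Numerical and design choices

- Strict `> T` at the threshold boundary; voxels equal to *T* excluded.
- 26-connectivity default in 3D: the conservative (merge-friendly) choice;
  configurable because slice-level SI analyses conventionally use 2D.
- The 10-voxel minimum applies as in-plane pixel counts in 2D mode.
- Coordinates are 0-based `(row, column, slice)` everywhere.
- Voxel volume excludes the inter-slice gap by default; with `include_gap`
  each voxel is credited thickness × (1 + gap). Published volumetry rarely
  states this convention, so both are exposed and the choice is recorded in
  run manifests.
- Degenerate inputs: empty ROI, all-equal reference labels for ROC, zero
  rank variance for Spearman, and inconsistent aggregate counts all raise
  with specific messages; an empty lesion set is a valid result (volume 0,
  absent intensity summaries).
- Problem sizes in the test and acceptance suites (64×64×12 phantoms,
  cohorts of 6, 10–20 seeds per property) were chosen as the smallest
  sizes at which the Gaussian-tail arguments above are comfortably
  non-marginal; all suites complete in well under a minute.

## Known limitations

- No bias-field correction; the bias phantom exists to demonstrate the
  failure mode, not to fix it.
- No automatic bone-marrow segmentation; masks are inputs.
- Thresholding cannot distinguish edema from other bright-marrow
  pathologies; it quantifies hyper-intensity, not diagnosis.
- DICOM support is read-only and assumes a single consistent series per
  directory.
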