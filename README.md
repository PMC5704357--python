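# stirquant

Threshold-based quantification of bone-marrow inflammatory edema in STIR MR
images of the spine and sacroiliac (SI) joints.

## The problem

In axial inflammatory arthritis (psoriatic arthritis, spondyloarthritis),
active inflammation shows up on fat-suppressed STIR MRI as bone-marrow
edema: marrow regions brighter than normal marrow. The clinical standard
for grading it, the SPARCC index, is a semi-quantitative score assigned by
a trained reader — reliable, but labor-intensive, reader-dependent, and it
only scores a selection of slices. `stirquant` implements the computer-aided
alternative: intensity thresholding of the full segmented bone-marrow
volume, yielding lesion volumes in cm³ and relative signal intensities that
can be compared against, or substitute for, reader scores.

It is a library plus a CLI, aimed at imaging researchers who have STIR
volumes and bone-marrow segmentations and want reproducible, quantitative
inflammation measures — and at methodologists who want to study the
behaviour of the thresholding approach itself on synthetic phantoms.

## The method

Given a STIR volume, a binary bone-marrow mask on the same voxel grid, and
a reference region of interest (ROI, ≥ 200 voxels) drawn in visibly normal
marrow:

1. *(optional)* histogram-match the volume to a common reference image so
   all image sets share one intensity scale;
2. compute the ROI mean *m* and sample SD *s*, and the threshold
   **T = m + k·s**, with *k* = 4.15 for the spine and *k* = 2.64 for the SI
   joints (ROC-calibrated operating points; any *k* can be supplied);
3. select bone-marrow voxels with intensity strictly above *T*;
4. group them into connected components (26-connectivity by default) and
   discard components of fewer than 10 voxels as noise artefacts — each
   surviving component is one lesion;
5. report **volume_hyper** (total lesion volume, cm³), the lesion count,
   and summaries (mean, median, 75th, 90th percentile) of the per-voxel
   relative intensity **S_RelHyper = (S_hyper − m) / m** pooled over all
   lesion voxels.

The `calibration` module sweeps *k* over a labelled cohort and picks the
operating point by Youden's J from the resulting ROC curve; the `agreement`
module computes confusion tables, sensitivity/specificity and Spearman rank
correlations against reference scores; the `phantom` module generates
synthetic STIR-like volumes (noisy marrow, elliptical lesions of controlled
contrast, optional coil-bias field) with exact ground truth.

## Worked example

Simulate a small labelled cohort (two phantoms with a 10 σ lesion, one
lesion-free), quantify one set at the spine preset, and calibrate *k*:

```sh
$ stirquant simulate --out-dir demo --seed 7 --n-positive 2 --n-negative 1
wrote 3 phantom sets to demo

$ stirquant quantify --image demo/set000_image.nii.gz \
    --bone-mask demo/set000_bone.nii.gz --roi demo/set000_roi.csv \
    --preset spine --out demo/set000_result.json
volume_hyper = 3.084 cm^3, n_objects = 1

$ stirquant calibrate --cases demo/manifest.csv \
    --k-min 1 --k-max 6 --k-step 0.5 --out demo/roc.csv
AUC = 1.000, optimal k = 6.0
```

`demo/set000_result.json` holds the full summary:

```json
{
  "volume_hyper_cm3": 3.084,
  "n_objects": 1,
  "s_rel_mean": 0.9897707216772555,
  "s_rel_median": 0.9885473931891487,
  "s_rel_p75": 1.0540243969013021,
  "s_rel_p90": 1.1134712014661008,
  "roi_mean": 100.47188553986726,
  "roi_sd": 10.949017709876873,
  "roi_n": 216,
  "threshold": 145.9103090358563,
  "k": 4.15
}
```

Reading this: the reference ROI (216 voxels) estimated normal marrow at
100.5 ± 10.9, so the spine threshold is 100.5 + 4.15 × 10.9 ≈ 145.9. One
lesion survived the 10-voxel filter, occupying 3.084 cm³ (771 voxels of
0.004 cm³), with mean relative intensity ≈ 0.99 — lesion voxels are on
average about twice as bright as normal marrow, as expected for a phantom
lesion drawn at contrast 10 σ = 100 units over a 100-unit marrow baseline.
On this perfectly separable cohort the ROC sweep reaches AUC 1.0, and the
Youden tie-break selects the largest separating *k* on the grid.

`stirquant run` batch-processes an inventory CSV and `stirquant agree`
compares the per-set results with a reference-score table; see
`stirquant --help`.

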