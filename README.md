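# dpratio

Morphometry of the pancreas and its main duct from CT segmentation
masks: the **duct-to-parenchyma area ratio (DP ratio)** measured on
cross-sections perpendicular to an automatically estimated pancreas
centerline, summarized per case by its **90th percentile** ("90th DP
ratio").

Two of the earliest imaging findings of pancreatic cancer are **main
pancreatic duct dilation (MPDD)** and **pancreatic parenchymal atrophy
(PPA)**.  Both change the same local quantity in opposite directions of
the same fraction: on a plane perpendicular to the organ's axis,

```
DP(s) = A_duct(s) / A_parenchyma(s)
```

rises where the duct is dilated (numerator grows) *and* where the
parenchyma is focally atrophic (denominator shrinks), so a single score
can screen for both findings.  The per-case score is the 90th
percentile of DP(s) over all cross-sections — high enough to respond to
a focal lesion spanning a modest fraction of the organ, low enough to
shrug off occasional outlier sections caused by segmentation or
centerline defects.

The package is aimed at researchers who already have binary pancreas
and duct masks (e.g. from a segmentation CNN) and want the shape
feature, plus a fully synthetic test bed: a phantom generator whose
circular cross-sections give the DP profile in closed form,
`DP(s) = r(s)^2 / (R(s)^2 - r(s)^2)`, so every pipeline stage can be
validated without clinical data.

## Method

1. **Centerline** — Euclidean distance transform of the pancreas mask;
   the two geodesically farthest voxels (snapped onto the medial ridge)
   are routed with Dijkstra's algorithm on the 26-connected voxel graph
   under the medialness cost `step_mm / (1 + D(v))^2`, ordered
   tail→head (the pancreatic tail is the patient-left end).
2. **Framing** — the voxel path is smoothed by a ±2-point moving
   average, resampled at 0.5 mm arc steps, tangents taken as chords to
   the point 10 mm ahead (local wiggle would otherwise tilt the
   planes), and normal/binormal vectors propagated as a
   rotation-minimizing frame.
3. **DP profile** — each mask is resampled on the normal×binormal plane
   (nearest neighbor, 0.5 mm pixels, ±40 mm); in-plane connected
   regions the centerline does not pierce are removed; the section's
   ratio is duct area over parenchyma area (pancreas minus duct by
   default).
4. **Score & statistics** — 90th percentile of the valid sections;
   cohort evaluation with Welch's t-test, ROC/AUROC, operating points
   at 90% sensitivity/specificity floors, and a Bonferroni-corrected
   (α/3) three-group comparison.

## Worked example

```sh
python examples/score_single_phantom.py
```

```
healthy        90th DP ratio = 0.0434   (analytic 0.0417, 162 valid sections)
dilated duct   90th DP ratio = 0.5677   (analytic 0.5625, 162 valid sections)
```

The healthy tube (R = 10 mm, concentric r = 2 mm duct) measures within
a few percent of the closed form 4/96 ≈ 0.0417; tripling the duct
radius over the middle third sends the 90th percentile to the dilated
plateau 36/64 ≈ 0.5625 — an order-of-magnitude separation.
`examples/profile_vs_ground_truth.py` shows per-section agreement along
a ramped duct, and `examples/cohort_evaluation.py` wires the cohort
statistics:

```
mean score with dilation    0.5990 (range 0.5640-0.6276)
mean score without dilation 0.0550 (range 0.0522-0.0634)
Welch p = 1.20e-11,  AUROC = 1.000
threshold 0.5640: sensitivity 1.00, specificity 1.00
```

From the shell, the same workflow is available as a thin CLI:

```sh
dpratio phantom --kind mpdd --n-positive 5 --n-negative 5 --out-dir ph/
dpratio cohort --cases ph/cases.csv --out-dir eval/
dpratio compute --pancreas pancreas.nii.gz --duct duct.nii.gz
```

Masks are NIfTI (MetaImage also accepted on input) and are reoriented
on load into a fixed patient-axis convention; case reports are JSON,
profiles and cohort tables CSV.

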