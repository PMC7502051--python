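# aortaqc

Automatic image-contrast quality measurement for aortic contrast-enhanced
CT angiography (CTA) volumes.

## The problem

Iodinated contrast agent makes vessels visible in CTA but carries real
patient risk (nephropathy, allergic reactions), so radiology departments
want to know — per study — whether the injected dose produced
*insufficient*, *optimal* or *excessive* vascular enhancement. The manual
protocol has an expert place three regions of interest (ROIs) on axial
slices and judge the mean Hounsfield units (HU) inside them:

* **ROI 1** — aorta at the level of the pulmonary artery bifurcation,
* **ROI 2** — aorta at kidney level,
* **ROI 3** — common femoral artery (arteria femoralis communis).

`aortaqc` automates that assessment end to end:

1. **Slice detection.** Each ROI's slice of interest (SOI) is found by
   template matching with zero-mean normalized cross-correlation (NCC):
   SOI 1 from a pulmonary-bifurcation patch searched over the upper two
   thirds of the volume, SOI 3 from left/right femoral-head patch *sets*
   (mean of the members' best matches) over the lower two thirds. A best
   similarity below 0.6 declares an SOI non-existing. SOI 2 is the rounded
   mean of SOI 1 and 3, or — when one of them is missing — a fixed 230 mm
   (46 slices at 5 mm z-spacing) offset from the one that exists.
2. **ROI localization.** On SOI 1 and 2 a circle Hough transform proposes
   up to six circle candidates per slice, and a dynamic program links
   candidates over five adjacent slices with the per-slice cost

   `C(x_ki) = C_v(x_ki) + C_r(x_k,i-1, x_ki) + C_d(x_k,i-1, x_ki)`

   (HU variance inside the circle, radius change, center distance). The
   minimum-cost path identifies the aorta — the structure most constant
   through the stack; if no path scores below 200 the circle is left to
   the reader. The measured disc radius is reduced by 4 px to keep wall
   calcification out of the mean. ROI 3 comes from a 2D multiscale
   Hessian vesselness filter on SOI 3 with bone/calcification excluded by
   HU thresholding and an anterior-medial search band anchored at the
   femoral-head template hits.
3. **Classification.** Each ROI mean is binned into expert categories
   A (≤180 HU), B (181–240), C (241–300, target), D (301–360), E (>360),
   and the combination mapped to class 1 (insufficient: any A), class 2
   (optimal: all in B/C/D) or class 3 (excessive: at least one E, the rest
   in D). Combinations the rules do not cover are reported as
   *indeterminate* rather than guessed; with two ROIs the same rules apply
   to the pair.

Because no clinical data ships with the package, `aortaqc.phantom`
generates synthetic CTA phantoms (aorta tube, bifurcation and femoral-head
landmarks, femoral arteries, vertebral decoy, optional calcification,
configurable lumen HU and noise) with exactly known ground truth; the test
suite validates every stage against brute-force oracles on them.

## Worked example

Generate a phantom with its template bank, then assess it:

```sh
$ aortaqc make-phantom demo --seed 5
INFO aortaqc: phantom written to demo (expected class: 2)

$ aortaqc assess demo/phantom.nrrd demo/bank --out demo/report.json
INFO aortaqc: report written to demo/report.json
INFO aortaqc: contrast class: 2 (all ROIs in B, C or D (C/C/C))
```

The report records every intermediate decision; the key fields of
`demo/report.json` read:

```json
{
  "status": "ok",
  "classification": {
    "class": "2",
    "matched_rule": "all ROIs in B, C or D (C/C/C)",
    "n_rois_used": 3
  },
  "sois": [
    {"soi_id": 1, "status": "found", "slice_index": 20, "best_similarity": 1.0},
    {"soi_id": 2, "status": "derived_mean", "slice_index": 46},
    {"soi_id": 3, "status": "found", "slice_index": 72, "best_similarity": 1.0}
  ]
}
```

All three ROI means land in category C (target area, 241–300 HU), so the
study is class 2 — optimal contrast. Exit codes of `assess`: 0 for a
determinate class, 3 for an indeterminate category combination, 4 when
fewer than two ROIs were measurable (manual review), 5 for I/O errors.

Input volumes can be a DICOM series directory (rescale slope/intercept
applied; series without rescale or spacing tags are rejected), NRRD or
NIfTI-1 already in HU. Volumes are canonicalized at load time: slice index
increases toward the feet, row index toward the anterior, column index
toward the patient's left.

Every tunable (thresholds, radius ranges, rule boundaries) lives in a
single YAML configuration whose committed defaults
(`src/aortaqc/data/defaults.yaml`) mirror the published parameters of the
method; pass `--config my.yaml` to override.

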