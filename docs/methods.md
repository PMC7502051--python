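# Methods

This note documents the models, conventions and numerical choices behind
`aortaqc`, in the order the pipeline runs them, followed by what the
synthetic phantoms do and do not establish.

## Canonical volume representation

All stages operate on a 3D HU array indexed `(slice, row, col)` with slice
index increasing inferior (head → feet), row index increasing anterior and
column index increasing toward the patient's left. The direction-dependent
parts of the method — the "upper/lower two thirds" SOI search spaces, the
±offset SOI-2 fallback, the anterior-medial femoral band — are defined
relative to this frame, so it is fixed once at load time (DICOM series are
sorted by physical position and flipped as needed; single-file volumes are
reoriented from their direction matrix). Volumes that cannot be mapped to
HU (DICOM without rescale tags) are rejected outright: the category
boundaries and the bone threshold are HU-absolute, and a silent default
would corrupt every downstream decision. Indexing is 0-based with
half-open intervals throughout.

## Slice detection

*Similarity.* The NCC is the zero-mean, unit-norm (Pearson) form — the
variant invariant to positive-gain affine intensity maps, which is the
point of using NCC here: contrast-filled structures vary strongly in
absolute HU between studies but little in spatial pattern. A zero-variance
image window is defined to score 0 (a flat patch carries no pattern); a
zero-variance template is a configuration error. The sliding evaluation
uses full-overlap windows only, stride 1 px: padding would bias the window
statistics at the borders. Internally the numerator is an FFT correlation
and the window mean/variance come from box sums; the result is the exact
windowed Pearson correlation (the test suite checks it against a direct
per-window evaluation to 1e-7).

*Search.* Templates are resampled to the target volume's in-plane spacing
with linear interpolation before matching. SOI 1 is searched over the
smallest ⌈2n/3⌉ slice indices, SOI 3 over the largest ⌈2n/3⌉ (no rounding
convention is canonical here; ceiling was chosen and is applied
symmetrically). A template set (left + right femoral head) scores the mean
of its members' best matches. The winner is the argmax over
(slice, candidate set); ties break toward the smaller slice index. The
existence threshold 0.6 is inclusive: only a best similarity strictly
below it declares an SOI non-existing. It is applied to the overall best
similarity, not per set.

*SOI 2.* With both neighbors found, SOI 2 is the arithmetic mean of SOI 1
and SOI 3 rounded half up. With one missing, a fixed physical offset of
230 mm — half the average SOI1–SOI3 distance, 46 slices at the 5 mm
z-spacing the method was developed on — is applied toward the missing
side; for other z-spacings the physical default is converted and rounded
to slices. Results falling outside the volume are clamped and flagged.

## Aortic ROI: circle Hough transform + dynamic programming

*Edge extraction.* Edge magnitude per axis is the larger of the forward
and backward one-sided differences, so an ideal HU step of height *h*
measures *h* HU/px at both flanking pixels. This keeps the default edge
threshold (100 HU/px) meaningful for low-contrast lumina: a 150 HU lumen
on 40 HU soft tissue measures 110 ≥ 100, whereas a central difference
would halve it to 55 and drop the vessel entirely. Vote *directions* come
from the gradient of a σ = 1 px Gaussian-smoothed copy: on hard rims the
raw finite differences quantize direction so coarsely that radial votes
scatter tangentially and the accumulator peak collapses.

*Voting.* Each edge pixel votes, for every radius in the configured
physiological range (default 8–25 mm, converted to px), at the two points
one radius away along its gradient direction; accumulator resolution is
1 px in center and radius. Each radius plane is normalized by the
circumference 2πr — the vote count of an ideal full circle — making peak
scores comparable across radii and interpretable as "fraction of a circle
supported". The six highest peaks after non-maximum suppression (minimum
center separation = smallest radius) become candidates. Peaks below a
minimum normalized score (default 0.1, i.e. less than a tenth of a
circumference of support) are discarded: such peaks are stray-vote
artifacts, and because they are deterministic functions of the anatomy
they can persist across adjacent slices and form spurious zero-variance,
zero-motion paths that would outscore the true aorta.

*Path cost.* Candidates on the SOI slice and the four slices inferior to
it (both aortic SOIs have the aorta continuing caudally) form a layered
graph; a standard dynamic program finds the minimum-cost path. The
per-slice cost sums three terms: the HU variance inside the circle divided
by v0 (default 100 HU², an explicit calibration — the method's printed
threshold of 200 is only meaningful once the variance term is put on a
scale commensurate with the pixel-unit radius and distance terms), the
absolute radius difference to the predecessor (px) and the Euclidean
center distance (px). The first slice of a path has no predecessor and
carries only the variance term. The variance is evaluated on the disc
shrunk by 1 px: centers and radii are pixel-quantized, and without the
shrink a perfectly detected lumen would be charged a large spurious
variance for the boundary pixels it clips. A path is accepted only if its
total cost is strictly below the threshold (default 200); otherwise no
circle is returned and the study is flagged for the reader. Near the
volume end the path truncates (minimum 3 layers) and the threshold scales
proportionally (200 × length/5). With default v0 a heavily calcified
vessel wall can push the variance term above the threshold; this is the
intended conservative behavior (fall back to the reader), not a failure
mode.

*Measurement.* The ROI is the SOI-slice disc of the selected path with its
radius reduced by 4 px (floor 1 px), keeping wall calcification outside
the measured mean. The reduction is applied in pixels exactly as the
method prescribes, not in mm.

## Femoral ROI: 2D multiscale vesselness

At each scale s (defaults 1–4 mm, converted to px) the slice is smoothed
with a Gaussian and the Hessian eigenvalues computed (reflective
boundaries; the response is scale-normalized by s²). The response is
−λ₂ wherever *both* eigenvalues are non-positive, zero elsewhere, and the
per-pixel maximum over scales is normalized to [0, 1]. Demanding both
eigenvalues non-positive restricts the response to the interior of bright
blobs and ridges: outside a bright disc the radial second derivative turns
positive in the smoothed tail, so the halo that a bare −λ₂ response drags
around every vessel is cut off. A constant slice maps to all zeros (an
absolute floor prevents discretization noise from being normalized up).

Bone and calcification (HU > 600, a conventional cortical-bone floor,
dilated by 2 px) are zeroed in the response before region finding.
Candidate regions are connected components above `min_response` (0.1).
Two anatomical filters then apply: the region peak must lie in an
anterior-medial band (default 0–30 px anterior, 6–30 px medial) of a
femoral-head template hit — template hits locate the head only to a few
px, hence the 6 px medial minimum that keeps responses at the head itself
out — and the region must not touch the dilated bone mask, since a
response attached to cortical bone is trabecular or partial-volume
structure, not a vessel lumen. Among the survivors the highest peak wins.
The ROI mask is the part of the region whose response *at the peak's
winning scale* exceeds half the peak: measuring at the detected scale
keeps the mask inside the lumen, where a half-peak cut on the
max-over-scales map would bleed large-scale response past the vessel wall
and dilute the mean with background. If nothing survives, ROI 3 is
omitted and the classifier runs on two ROIs.

On clinical data this stage is known to be the weakest component of the
approach; it is implemented as designed, with the spatial prior and all
thresholds exposed in the configuration.

## Classification

Categories: A ⇔ HU ≤ 180, B ⇔ 181–240, C ⇔ 241–300 (target),
D ⇔ 301–360, E ⇔ > 360. Real-valued means are binned by the same
inequalities (≤ 180 → A; < 241 → B; < 301 → C; < 361 → D; else E), so
180.5 is B and 360.5 is D, consistent with the printed integer ranges.

Class rules are evaluated literally over however many ROIs are present
(2 or 3): class 1 if any ROI is in A; class 2 if all are in B/C/D;
class 3 if at least one is in E and the *remaining* ROIs are all in D.
The class-3 condition is read non-vacuously: it requires at least one
non-E ROI, so an all-E study matches no rule. Exhaustive enumeration
(125 three-ROI + 25 two-ROI combinations, checked in the tests) shows the
three rules are mutually exclusive and that every uncovered combination
contains an E and no A. Those combinations are reported as
*indeterminate* by default — the guarantee that a class-3 call is always
truly excessive rests on the rule being exactly this narrow — and an
optional `total_coverage` mode maps them to class 3 for users who prefer
a total function.

## Synthetic phantoms

The phantom generator renders, on a uniform 40 HU soft-tissue background
(default 96×128×128 voxels at 1×1×5 mm): an aortic tube with a gentle
sinusoidal center drift and per-segment lumen HU; a three-lobe
pulmonary-bifurcation-like pattern on one slice; paired femoral heads
rendered as a 700 HU cortical shell (radius 14 px) over a 300 HU
trabecular interior; 3 px femoral arteries anterior-medial to the heads;
a vertebral-body decoy (400 HU with a 150 HU core) running the whole
stack; an optional 2 px 1000 HU calcification ring on the aortic wall;
and additive Gaussian noise (default σ = 10 HU, a realistic soft-tissue
noise level) that is the only seeded randomness — geometry is
deterministic.

Two rendering choices matter for testability. Structures are painted as
hard-edged discs by center-of-voxel inclusion, which makes brute-force
oracles exact. And the bright circular structures are given internal
structure (head shell + interior, vertebral core) so that they are nearly
orthogonal under NCC: a solid-disc femoral head at a radius similar to the
aorta's would pseudo-match any bright disc at ~0.85 similarity, and no
0.6 existence threshold could then distinguish a present landmark from an
absent one — real femoral heads and vertebral bodies likewise match a
plain bright disc poorly because of their cortical/trabecular structure.

Ground-truth ROI means are measured on the *rendered* voxels inside the
ground-truth masks (aortic discs after the 4 px reduction; the artery-disc
union for ROI 3), never taken from the nominal lumen HU, and expected
categories/classes are recomputed through the classifier, keeping the rule
tables a single source of truth.

What the phantoms do not emulate: CT physics (beam hardening, streaks,
partial volume at 5 mm slices), anatomical variability and pathology
(aneurysm, dissection — the main cause of aortic-localization failure on
clinical data), surrounding organs and vessels that act as circle or
vesselness confounders, and patient-to-patient landmark appearance
variation beyond small template jitter. Passing the suite therefore
demonstrates algorithmic correctness (each stage equals its brute-force
oracle, the rules are implemented exactly, the pipeline recovers known
ground truth under noise), not clinical-grade accuracy.

## Problem sizes and determinism

The default phantom (96 slices of 128×128) keeps a full assessment at a
few seconds; the acceptance cohort (24 phantoms spanning the five
categories, the class-3 configurations and the two-ROI pathway, with the
template bank drawn from a separate reference phantom) runs in about a
minute. All randomness flows from explicit integer seeds; repeated
assessments of the same inputs produce byte-identical reports.

## Known limitations

* The Hough stage assumes a quasi-circular aortic cross-section; strongly
  deformed aortas (dissection flaps, large aneurysms) violate the model
  and are expected to fall back to the reader via the cost threshold.
* The femoral vesselness stage inherits the approach's known weakness on
  small vessels; the anterior-medial band and bone-adjacency filters make
  it reliable on phantoms but are no substitute for a proper segmentation.
* v0 (variance normalization) and the Hough minimum score are package
  calibrations, not published values; both are configuration keys.
* Multi-frame (enhanced) DICOM, gantry-tilted and non-axially acquired
  series are rejected rather than resampled.
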