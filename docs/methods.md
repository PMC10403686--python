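# Methods

This note documents the models, conventions and numerical choices behind
`focalmargin`, and what its synthetic experiments do and do not establish.

## Grids, masks and distances

All volumes of a case share one axis-aligned voxel grid (x to
patient-left, y to anterior, z apex-to-base); inputs on mismatched grids
are rejected rather than resampled. Masks use voxel-center semantics: a
voxel belongs to a region iff its center does. Distances are Euclidean in
mm with anisotropic spacing respected (`scipy.ndimage`
distance transforms). Phantoms default to isotropic 1 mm on a 64³ grid —
close to in-plane T2 resolution, and small enough that exhaustive
brute-force oracles remain tractable in the tests.

Two distance conventions coexist deliberately:

- **Point-to-set distances** (missed-cancer extent, ROI expansion) are
  center-to-center. The 10-mm ROI expansion is the closed ball
  `{distance ≤ r}`, boundary ties included.
- **Set-to-set gaps** (the "satellite if ≥ 2 mm from the index" rule) are
  *surface* distances: the center distance minus each voxel box's extent
  along the connecting direction (its support function). Two 1-mm voxels
  separated by one empty voxel are 1 mm apart, not 2. Without this
  correction the satellite-merge rule and the phantom's satellite
  placement guarantee would disagree at the voxel scale.

Connected components default to 26-connectivity so diagonal-touching
tumor voxels form one focus; labels are deterministic (decreasing size,
ties by first linear index).

## Phantom cohort model

Each case is drawn independently:

- **Gland**: ellipsoid with lognormal volume (median 33.4 cc, σ = 0.30),
  mild random anisotropy, plus a smoothed Gaussian deformation field;
  largest component, holes filled. PSA is lognormal (median 6.9 ng/ml,
  σ = 0.35). These centers follow a prostatectomy-candidate population.
- **Index lesion**: deformed ellipsoid, lognormal volume (median 1.3 cc,
  σ = 0.5), ISUP grade 3 with probability 0.4 (else grade 2), seeded in
  the gland interior. With probability 0.25 it is allowed to cross the
  sagittal midline; otherwise it is clipped to one side.
- **Satellites**: 0/1/2 with probabilities 0.50/0.35/0.15; lognormal
  volume (median 0.15 cc); ISUP grade 2 with probability 0.5, else grade
  1. Grade-1 satellites are *excluded* from the significant-cancer ground
  truth, emulating lesions that upgrade only on final pathology — the
  dominant failure mode of margins planned from biopsy evidence. All
  satellite voxels are carved to keep a surface gap ≥ 2 mm from the index
  (center-distance carve padded by one voxel diagonal, conservative in
  every direction).
- **ROI**: erosion of the index lesion by a depth drawn from
  N(5, 1.5²) mm (min 2 mm), relaxed until nonempty. This guarantees the
  headline failure mode — ROI ⊂ index lesion — in every case. Because
  the package asserts ROI ⊆ index as an invariant, satellites carry no
  ROIs of their own; satellite evidence enters only through systematic
  cores. PI-RADS scores are sampled 3/4/5 with weights 0.15/0.56/0.29.
- **CEM**: logistic transform `expit(κ·s(x))` of the signed distance
  into the significant-cancer set (smoothed at 3 mm), plus a correlated
  Gaussian noise field (sd 0.08, correlation 4 mm), clipped to
  [0, 1 − 1e−6] and zeroed outside the gland. The fidelity parameter κ
  controls voxel-level discrimination monotonically. The default
  κ = 0.06/mm was fixed once from a sweep so that the mean per-case AUC
  of 100 default phantoms lands near 0.91 (measured 0.918 ± 0.006 across
  three seeds) — the regime of a strong but imperfect voxel classifier.
  The exclusive upper clip is a numerical convenience: probabilities of
  exactly 1 are avoided so the threshold-1 margin is empty by
  construction.
- **Cores**: 12 systematic cores (2 lateral positions per side × 3
  apex-to-base levels, posterior entry, 22 mm throws, jittered) plus one
  targeted core through each ROI centroid. Grades and cancer lengths are
  read from the lesion label map along the segment, so core pathology is
  always consistent with crossed lesions. The centroid of the
  significant-cancer-positive portion of each core is retained — the
  analog of a fusion platform's tracked location — and drives the
  hemisphere logic.
- **Slab**: 4 mm trimmed from the gland's apical and basal extremes,
  emulating the region between the first and last histology slides.
  Cases whose cancer falls entirely outside the slab are redrawn.

The **eligibility screen** applies three preoperative criteria: (1) at
least one ROI with a targeted core of ISUP grade 2–3; (2) all
significant-cancer evidence (positive-core centroids and confirmed-ROI
voxels) confined to one lateral hemisphere or the anterior half —
half-spaces through the gland centroid, with half-voxel tolerance; (3) no
prior treatment. Hemigland margin side selection reuses the same
evidence, preferring a lateral side over anterior on ties.

What the phantoms do **not** model: MRI texture and intensity, zonal
anatomy, deformable histology registration error, extraprostatic
extension, multifocal index lesions with more than two satellites, and
reader variability in ROI contours. A green test therefore establishes
that the *pipeline machinery* (thresholding, calibration, selection,
evaluation) behaves correctly under the stated statistical structure, not
that any clinical performance figure transfers to real patients.

## Margins

Threshold margins blur the binary superlevel-set indicator with an
isotropic Gaussian (σ = `smoothing_mm`, default 2 mm) and re-threshold at
0.5. This smoother was chosen because it is deterministic,
rotation-symmetric, and — being a positive linear operator followed by a
fixed threshold — exactly preserves set nesting, so margins shrink
monotonically as the CEM threshold rises. Before blurring, the superlevel
set is extended across the gland boundary by nearest-neighbor filling of
the CEM: without this, the zero exterior would erode margins wherever
cancer risk reaches the capsule, making full encapsulation impossible at
any positive threshold in capsule-abutting cases. The extension is
monotone, so nesting survives. Margins are clipped to the gland for
volume accounting (margin volume is reported as a fraction of the
prostate); the unclipped ROI expansion is available behind a flag.

Monotonicity has a useful computational consequence: per case, the
margin is negative exactly for thresholds up to a critical grid index,
found by binary search (7 margin evaluations instead of 101). The test
suite verifies this equals the direct per-threshold scan.

## ECS calibration and default margins

`ECS(t)` is the proportion of calibration cases whose margin at `t`
covers every slab-restricted significant-cancer voxel. Monotonicity is
enforced by cumulative minimum over ascending thresholds — chosen over
isotonic regression because it preserves the empirical proportions as
upper bounds and is order-preserving; with nested margins the enforcement
is a no-op up to ties, and the recorded deltas are bounded by one case's
worth of probability. The grid is 101 points (0.00–1.00, step 0.01), and
the lookup is evaluated on the grid only, without interpolation.

The default threshold maximizes `ECS(t) − λ·V(t)` with both terms on the
[0, 1] scale and λ = 1 by default; expressing the volume percent as a
fraction makes the objective scale-free. Ties break toward the larger
threshold (the smaller margin). A degenerate all-zero CEM yields an empty
default margin, which is flagged rather than raised.

## Evaluation conventions

All voxel metrics are computed on gland voxels within the slab.
`extent_missed_mm` is the **maximum** distance of any missed cancer voxel
from the margin set — penetration depth — because that is the quantity
commensurate with published maximum-underestimation figures; the mean
over missed voxels is reported secondarily. For an empty margin no margin
surface exists, so penetration is reported relative to the gland
boundary (distance of missed cancer from the gland exterior) and the
case is flagged. Encapsulation is adjudicated voxelwise (every truth
voxel center inside the margin), not surface-topologically, since truth
and margins share one lattice. Specificity's denominator is benign gland
voxels within the slab.

Cohort comparisons use Wilcoxon signed-rank tests on paired continuous
metrics and chi-square tests on negative-margin rates, against the
default-AI row; degenerate comparisons (identical margins, empty
contingency rows) report p = 1 by contract. Hemigland rows use only
hemigland-eligible cases and record their denominator. ECS accuracy on an
independent cohort is summarized by the least-squares fit of observed on
predicted rates (slope, intercept, R²), the median and IQR of absolute
error, and a two-sample Kolmogorov–Smirnov test; a constant predicted
curve reports R² as NaN with a warning.

## Stand-in predictor

The production-style model (a 3D CNN image branch feeding gradient-
boosted trees) cannot exist here: phantoms have no image intensities. The
stand-in keeps the ensemble structure — five fold models trained on
case-level fold complements, predictions averaged — and the engineered
feature classes: signed capsule depth, distance to the nearest ROI and
its PI-RADS score, per-core point-to-segment distance / grade / cancer
length / targeted flag for the k = 3 nearest cores, and PSA. Fold models
are `HistGradientBoostingClassifier`s (the gradient-boosted-tree family,
behind an interface accepting any probabilistic classifier). Voxel
training labels are taken from the ground-truth mask, subsampled 1:1
positive:negative per case (400 samples by default) — a documented
substitute for training on biopsy labels, which are too sparse at voxel
density. This is a fidelity limitation by design: the stand-in exercises
everything downstream of the probability map.

## Known limitations

- ECS calibration and transfer are demonstrated under i.i.d. phantom
  cohorts; distribution shift between calibration and deployment
  populations is out of scope.
- The ROI underestimation (mean 5 mm erosion) is fixed relative to
  phantom lesion sizes; raw-ROI sensitivity is therefore lower than
  clinical reports, though the qualitative ordering of margin strategies
  is preserved.
- Surface-distance corrections are exact for axis-aligned voxel boxes;
  sub-voxel lesion geometry is not represented.
- No mesh or device export; margins remain lattice masks.
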