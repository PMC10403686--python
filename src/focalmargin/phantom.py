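"""Synthetic prostate phantom cohorts for margin-planning experiments.

Real margin-planning pipelines consume co-registered MRI-derived volumes
(gland and ROI segmentations, a voxel-level cancer probability map) plus
tracked-biopsy records and PSA. No such dataset is publicly distributable,
so this module generates phantom cases that reproduce the *statistical
structure* the pipeline relies on:

* a gland (smoothed, randomly deformed ellipsoid) holding one index
  clinically-significant lesion that may cross the midline, plus 0-2
  satellite foci placed at least 2 mm from the index;
* an MRI-style ROI that systematically underestimates the index lesion
  (the ROI is a strict erosion of it);
* a cancer estimation map (CEM) whose voxel-level discrimination is tuned
  by a single fidelity parameter kappa;
* a 12-core systematic biopsy template plus one targeted core per ROI,
  with grades and cancer lengths read from the ground-truth lesions;
* an apex-to-base analysis slab emulating the region covered by
  whole-mount histology slides.

Satellites may be ISUP grade 1 (excluded from the significant-cancer
ground truth) to emulate lesions at risk of upgrade on final pathology.

Default distribution centres follow a prostatectomy-candidate population:
median gland volume 33.4 cc and median PSA 6.9 ng/ml, index grade ISUP 2
in 60% / ISUP 3 in 40% of cases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .voxelgeom import Mask, VoxelGrid

LATERAL_SIDES = ("left", "right")
HEMISPHERES = ("left", "right", "anterior")


# --------------------------------------------------------------------------
# domain types


@dataclass
class BiopsyCore:
    """A sampled biopsy needle segment with its pathology read-out.

    ``entry_mm``/``tip_mm`` are voxel-grid coordinates in mm. The sampled
    segment is the straight line between them. ``cs_centroid_mm`` is the
    centroid of the significant-cancer-positive portion of the segment
    (None if the core carries no ISUP >= 2 cancer); fusion platforms record
    the equivalent tracked location, so it is preoperative information.
    """

    core_id: str
    entry_mm: tuple[float, float, float]
    tip_mm: tuple[float, float, float]
    isup_grade: int
    cancer_length_mm: float
    targeted: bool
    roi_id: Optional[str] = None
    cs_centroid_mm: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.isup_grade not in range(6):
            raise ValueError(f"isup_grade must be 0..5, got {self.isup_grade}")
        if self.cancer_length_mm < 0:
            raise ValueError("cancer_length_mm must be >= 0")
        if self.isup_grade == 0 and self.cancer_length_mm > 0:
            raise ValueError("benign core cannot carry cancer length")
        seg = np.subtract(self.tip_mm, self.entry_mm)
        if self.cancer_length_mm > np.linalg.norm(seg) + 1e-6:
            raise ValueError("cancer_length_mm exceeds segment length")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.tip_mm, self.entry_mm)))


@dataclass
class RoiMask:
    """An MRI region of interest with its suspicion score (PI-RADS v2)."""

    roi_id: str
    mask: Mask
    pirads: int


@dataclass
class PatientCase:
    """One co-registered phantom case.

    ``lesion_labels`` holds 0 for background, 1 for the index lesion and
    2.. for satellites; ``lesion_grades`` maps those labels to ISUP grade
    groups. ``truth_cs`` is the union of lesions with grade >= 2. ``slab``
    is the inclusive z-index interval [z_apex, z_base] over which ground
    truth is considered known.
    """

    case_id: str
    grid: VoxelGrid
    gland: Mask
    truth_cs: Mask
    roi_list: list[RoiMask]
    cores: list[BiopsyCore]
    psa_ng_ml: float
    slab: tuple[int, int]
    cem: Optional[np.ndarray] = None
    lesion_labels: Optional[np.ndarray] = None
    lesion_grades: dict[int, int] = field(default_factory=dict)
    prior_treatment: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.psa_ng_ml <= 0:
            raise ValueError("PSA must be positive")
        if not self.truth_cs.issubset(self.gland):
            raise ValueError("truth_cs must lie inside the gland")
        for roi in self.roi_list:
            if not roi.mask.issubset(self.gland):
                raise ValueError(f"ROI {roi.roi_id} must lie inside the gland")
        z0, z1 = self.slab
        if not (0 <= z0 <= z1 < self.grid.shape[2]):
            raise ValueError(f"slab {self.slab} outside grid z-range")
        if self.cem is not None:
            self.attach_cem(self.cem)

    def attach_cem(self, cem: np.ndarray) -> None:
        cem = np.asarray(cem)
        if cem.shape != self.grid.shape:
            raise ValueError("CEM shape does not match case grid")
        inside = cem[self.gland.values]
        if inside.size and (inside.min() < 0 or inside.max() > 1):
            raise ValueError("CEM values on gland voxels must lie in [0, 1]")
        self.cem = cem.astype(np.float32, copy=False)

    @property
    def slab_mask(self) -> Mask:
        sel = np.zeros(self.grid.shape, dtype=bool)
        sel[:, :, self.slab[0]: self.slab[1] + 1] = True
        return Mask(self.grid, sel)

    def gland_centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.gland.values)
        return idx.mean(axis=0) * np.asarray(self.grid.spacing_mm)


@dataclass
class PhantomConfig:
    """Generator parameters; defaults define the reference phantom population."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # gland: lognormal volume, median 33.4 cc
    gland_volume_cc_median: float = 33.4
    gland_volume_cc_sigma: float = 0.30
    # index lesion: lognormal volume
    index_volume_cc_median: float = 1.3
    index_volume_cc_sigma: float = 0.50
    index_isup3_prob: float = 0.40  # else ISUP 2
    midline_crossing_prob: float = 0.25
    # satellites
    satellite_count_probs: tuple[float, ...] = (0.50, 0.35, 0.15)
    satellite_cs_prob: float = 0.50  # ISUP 2 if drawn, else ISUP 1
    satellite_volume_cc_median: float = 0.15
    satellite_volume_cc_sigma: float = 0.40
    satellite_min_gap_mm: float = 2.0
    # ROI underestimation: erosion depth of the index lesion, in mm
    roi_underestimation_mm_mean: float = 5.0
    roi_underestimation_mm_sd: float = 1.5
    roi_underestimation_mm_min: float = 2.0
    # CEM
    # 0.06/mm puts mean per-case voxel AUC near 0.91 at the default noise
    # level (chosen once from a kappa sweep; see docs/methods.md)
    cem_kappa_per_mm: float = 0.06
    cem_smoothness_mm: float = 3.0
    cem_noise_sd: float = 0.08
    cem_noise_corr_mm: float = 4.0
    # slab and clinical covariates
    slab_trim_mm: float = 4.0
    psa_median: float = 6.9
    psa_sigma: float = 0.35
    prior_treatment_prob: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.satellite_count_probs, dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("satellite_count_probs must be a probability vector")
        for name in ("midline_crossing_prob", "satellite_cs_prob",
                     "index_isup3_prob", "prior_treatment_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cem_kappa_per_mm < 0:
            raise ValueError("cem_kappa_per_mm must be >= 0")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(tuple(self.grid_shape), tuple(self.spacing_mm))


@dataclass
class EligibilityResult:
    eligible: bool
    criteria: dict[str, bool]
    reasons: list[str]


# --------------------------------------------------------------------------
# internal geometry helpers


def _smooth_noise(rng, shape, corr_vox, amplitude):
    """Gaussian random field with unit-normalized amplitude."""
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=corr_vox)
    sd = noise.std()
    if sd > 0:
        noise *= amplitude / sd
    return noise


def _ellipsoid_implicit(coords, center_mm, radii_mm):
    q = sum(((c - m) / r) ** 2 for c, m, r in zip(coords, center_mm, radii_mm))
    return 1.0 - q


def _radii_from_volume(volume_mm3, aniso):
    """Ellipsoid radii (mm) with given anisotropy factors and target volume."""
    aniso = np.asarray(aniso, dtype=float)
    aniso = aniso / np.prod(aniso) ** (1.0 / 3.0)
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r * aniso


def _largest_component(values: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(values, structure=ndimage.generate_binary_structure(3, 3))
    if n <= 1:
        return values
    counts = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(counts)) + 1)


# --------------------------------------------------------------------------
# case generation


def _sample_gland(cfg: PhantomConfig, rng) -> Mask:
    grid = cfg.grid
    coords = grid.coords_mm()
    extent = np.array(grid.shape) * np.array(grid.spacing_mm)
    volume = np.exp(rng.normal(np.log(cfg.gland_volume_cc_median * 1000.0),
                               cfg.gland_volume_cc_sigma))
    aniso = np.exp(rng.normal(0.0, 0.10, size=3))
    radii = _radii_from_volume(volume, aniso)
    center = extent / 2.0 + rng.normal(0.0, 1.0, size=3)
    f = _ellipsoid_implicit(coords, center, radii)
    corr = 8.0 / np.asarray(grid.spacing_mm)
    f = f + _smooth_noise(rng, grid.shape, corr, amplitude=0.15)
    values = f > 0
    values = _largest_component(values)
    values = ndimage.binary_fill_holes(values)
    # keep at least one clear voxel at each face so the capsule is closed
    values[0, :, :] = values[-1, :, :] = False
    values[:, 0, :] = values[:, -1, :] = False
    values[:, :, 0] = values[:, :, -1] = False
    if values.sum() < 100:
        raise RuntimeError("gland sampling produced a degenerate mask")
    return Mask(grid, values)


def _sample_lesion(cfg, rng, gland: Mask, volume_mm3, center_vox, aniso_sigma=0.35,
                   half_space=None):
    grid = gland.grid
    coords = grid.coords_mm()
    aniso = np.exp(rng.normal(0.0, aniso_sigma, size=3))
    radii = _radii_from_volume(volume_mm3, aniso)
    center = np.asarray(center_vox, dtype=float) * np.asarray(grid.spacing_mm)
    f = _ellipsoid_implicit(coords, center, radii)
    corr = 4.0 / np.asarray(grid.spacing_mm)
    f = f + _smooth_noise(rng, grid.shape, corr, amplitude=0.25)
    values = (f > 0) & gland.values
    if half_space is not None:
        values &= half_space
    if not values.any():
        return None
    values = _largest_component(values)
    return values


def _interior_candidates(gland: Mask, depth_mm: float) -> np.ndarray:
    depth = ndimage.distance_transform_edt(gland.values, sampling=gland.grid.spacing_mm)
    return np.argwhere(depth >= depth_mm)


def _sample_case_once(cfg: PhantomConfig, rng, case_id: str) -> PatientCase:
    grid = cfg.grid
    spacing = np.asarray(grid.spacing_mm)
    gland = _sample_gland(cfg, rng)
    gland_idx = np.argwhere(gland.values)
    centroid_vox = gland_idx.mean(axis=0)

    # ---- index lesion
    index_grade = 3 if rng.random() < cfg.index_isup3_prob else 2
    crosses_midline = rng.random() < cfg.midline_crossing_prob
    v_index = np.exp(rng.normal(np.log(cfg.index_volume_cc_median * 1000.0),
                                cfg.index_volume_cc_sigma))
    interior = _interior_candidates(gland, depth_mm=4.0)
    if interior.size == 0:
        interior = gland_idx
    index_values = None
    for _ in range(30):
        if crosses_midline:
            cand = interior[np.abs(interior[:, 0] - centroid_vox[0]) * spacing[0] <= 3.0]
            half_space = None
        else:
            side = 1 if rng.random() < 0.5 else -1
            off = np.abs(interior[:, 0] - centroid_vox[0]) * spacing[0]
            cand = interior[(np.sign(interior[:, 0] - centroid_vox[0]) == side) & (off >= 4.0)]
            xs = np.arange(grid.shape[0])
            hs_cols = (np.sign(xs - centroid_vox[0]) == side) | (xs == int(round(centroid_vox[0])))
            half_space = np.zeros(grid.shape, dtype=bool)
            half_space[hs_cols, :, :] = True
        if cand.size == 0:
            cand = interior
        center = cand[rng.integers(len(cand))]
        index_values = _sample_lesion(cfg, rng, gland, v_index, center,
                                      half_space=half_space)
        if index_values is not None and index_values.sum() >= 8:
            break
        index_values = None
    if index_values is None:
        raise RuntimeError("index lesion placement failed: no feasible interior seed")

    labels = np.zeros(grid.shape, dtype=np.int8)
    labels[index_values] = 1
    grades = {1: index_grade}

    # ---- satellites, kept >= min_gap from the index lesion boundary
    n_sat = int(rng.choice(len(cfg.satellite_count_probs), p=cfg.satellite_count_probs))
    index_dist = ndimage.distance_transform_edt(~index_values, sampling=grid.spacing_mm)
    # center-distance carve conservative by one voxel diagonal, so the
    # surface-to-surface gap is >= satellite_min_gap_mm in any direction
    gap_centers = cfg.satellite_min_gap_mm + float(np.linalg.norm(spacing))
    next_label = 2
    for _ in range(n_sat):
        grade = 2 if rng.random() < cfg.satellite_cs_prob else 1
        v_sat = np.exp(rng.normal(np.log(cfg.satellite_volume_cc_median * 1000.0),
                                  cfg.satellite_volume_cc_sigma))
        r_sat = (3.0 * v_sat / (4.0 * np.pi)) ** (1.0 / 3.0)
        placed = False
        for _ in range(30):
            ok = (index_dist[tuple(interior.T)] >= gap_centers + r_sat)
            cand = interior[ok]
            if cand.size == 0:
                break
            center = cand[rng.integers(len(cand))]
            sat = _sample_lesion(cfg, rng, gland, v_sat, center, aniso_sigma=0.25)
            if sat is None:
                continue
            sat &= index_dist >= gap_centers
            sat &= labels == 0
            if not sat.any():
                continue
            sat = _largest_component(sat)
            labels[sat] = next_label
            grades[next_label] = grade
            next_label += 1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "satellite placement failed: no location satisfies the "
                f"{cfg.satellite_min_gap_mm} mm gap from the index lesion"
            )

    truth_values = np.zeros(grid.shape, dtype=bool)
    for lab, g in grades.items():
        if g >= 2:
            truth_values |= labels == lab
    truth_cs = Mask(grid, truth_values)

    # ---- ROI: strict erosion of the index lesion (MRI underestimation)
    depth = ndimage.distance_transform_edt(index_values, sampling=grid.spacing_mm)
    m = max(cfg.roi_underestimation_mm_min,
            rng.normal(cfg.roi_underestimation_mm_mean, cfg.roi_underestimation_mm_sd))
    roi_values = depth > m
    while not roi_values.any() and m > 0.5:
        m -= 1.0
        roi_values = depth > m
    if not roi_values.any():
        peak = np.unravel_index(np.argmax(depth), depth.shape)
        roi_values = np.zeros(grid.shape, dtype=bool)
        roi_values[peak] = True
    roi_values = _largest_component(roi_values)
    pirads = int(rng.choice((3, 4, 5), p=(0.15, 0.56, 0.29)))
    roi_list = [RoiMask("roi1", Mask(grid, roi_values), pirads)]

    # ---- CEM: logistic of smoothed signed distance into truth, plus noise
    sd_in = ndimage.distance_transform_edt(truth_values, sampling=grid.spacing_mm)
    sd_out = ndimage.distance_transform_edt(~truth_values, sampling=grid.spacing_mm)
    signed = sd_in - sd_out
    signed = ndimage.gaussian_filter(signed, sigma=cfg.cem_smoothness_mm / spacing)
    cem = expit(cfg.cem_kappa_per_mm * signed)
    if cfg.cem_noise_sd > 0:
        cem = cem + _smooth_noise(rng, grid.shape, cfg.cem_noise_corr_mm / spacing,
                                  cfg.cem_noise_sd)
    # probabilities of exactly 1 are avoided so the top threshold stays empty
    cem = np.clip(cem, 0.0, 1.0 - 1e-6)
    cem[~gland.values] = 0.0
    cem = cem.astype(np.float32)

    # ---- slab
    zs = np.flatnonzero(gland.values.any(axis=(0, 1)))
    trim = int(np.ceil(cfg.slab_trim_mm / spacing[2]))
    z0, z1 = int(zs[0]) + trim, int(zs[-1]) - trim
    if z0 > z1:
        raise RuntimeError("slab trim removed the whole gland")
    if not truth_values[:, :, z0:z1 + 1].any():
        raise RuntimeError("significant cancer lies entirely outside the slab")

    psa = float(np.exp(rng.normal(np.log(cfg.psa_median), cfg.psa_sigma)))
    prior = bool(rng.random() < cfg.prior_treatment_prob)

    cores = _sample_cores(cfg, rng, gland, labels, grades, roi_list)

    return PatientCase(
        case_id=case_id, grid=grid, gland=gland, truth_cs=truth_cs,
        roi_list=roi_list, cores=cores, psa_ng_ml=psa, slab=(z0, z1),
        cem=cem, lesion_labels=labels, lesion_grades=grades,
        prior_treatment=prior,
    )


def _read_core(grid: VoxelGrid, labels, grades, entry_mm, tip_mm, core_id,
               targeted, roi_id=None, step_mm=0.25) -> BiopsyCore:
    entry = np.asarray(entry_mm, dtype=float)
    tip = np.asarray(tip_mm, dtype=float)
    length = np.linalg.norm(tip - entry)
    n = max(2, int(np.ceil(length / step_mm)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = entry[None, :] + ts[:, None] * (tip - entry)[None, :]
    idx = np.round(pts / np.asarray(grid.spacing_mm)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    lab = np.zeros(n, dtype=int)
    lab[inside] = labels[tuple(idx[inside].T)]
    seg = length / (n - 1)
    hit = lab > 0
    cancer_len = float(hit.sum() * seg)
    grade = max((grades[l] for l in np.unique(lab[hit])), default=0)
    if grade == 0:
        cancer_len = 0.0
    cancer_len = min(cancer_len, float(length))
    cs_hit = np.array([h and grades[l] >= 2 for h, l in zip(hit, lab)])
    cs_centroid = tuple(pts[cs_hit].mean(axis=0)) if cs_hit.any() else None
    return BiopsyCore(core_id, tuple(entry), tuple(tip), grade, cancer_len,
                      targeted, roi_id, cs_centroid)


def _sample_cores(cfg, rng, gland: Mask, labels, grades, roi_list) -> list[BiopsyCore]:
    """12-core sextant-derived systematic template plus one core per ROI.

    Systematic cores run posterior-to-anterior at 2 lateral x 2 medial
    positions per side x 3 levels (apex/mid/base); targeted cores pass
    through the ROI centroid.
    """
    grid = gland.grid
    spacing = np.asarray(grid.spacing_mm)
    idx = np.argwhere(gland.values)
    lo = idx.min(axis=0) * spacing
    hi = idx.max(axis=0) * spacing
    c = idx.mean(axis=0) * spacing
    cores = []
    n = 1
    for sx in (-1, +1):
        half_w = (hi[0] - c[0]) if sx > 0 else (c[0] - lo[0])
        for fx in (0.3, 0.65):
            x = c[0] + sx * fx * half_w
            for fz in (0.25, 0.5, 0.75):
                z = lo[2] + fz * (hi[2] - lo[2])
                jitter = rng.normal(0.0, 0.8, size=2)
                entry = (x + jitter[0], lo[1] - 2.0, z + jitter[1])
                tip = (entry[0], entry[1] + 22.0, entry[2])
                cores.append(_read_core(grid, labels, grades, entry, tip,
                                        f"sys{n:02d}", targeted=False))
                n += 1
    for roi in roi_list:
        cen = np.argwhere(roi.mask.values).mean(axis=0) * spacing
        entry = (cen[0], cen[1] - 11.0, cen[2])
        tip = (cen[0], cen[1] + 11.0, cen[2])
        cores.append(_read_core(grid, labels, grades, entry, tip,
                                f"tgt_{roi.roi_id}", targeted=True,
                                roi_id=roi.roi_id))
    return cores


def sample_case(config: PhantomConfig, rng: np.random.Generator,
                case_id: str = "case0000", max_retries: int = 5) -> PatientCase:
    """Draw one phantom case; bounded retries on infeasible geometry."""
    last = None
    for _ in range(max_retries):
        try:
            return _sample_case_once(config, rng, case_id)
        except RuntimeError as exc:  # infeasible placement; re-draw
            last = exc
    raise RuntimeError(f"case sampling failed after {max_retries} attempts: {last}")


# --------------------------------------------------------------------------
# focal-therapy eligibility screen


def _cs_evidence_points(case: PatientCase) -> list[np.ndarray]:
    """Preoperative significant-cancer evidence: positive-core centroids and
    voxels of biopsy-confirmed ROIs."""
    pts = [np.asarray(core.cs_centroid_mm) for core in case.cores
           if core.isup_grade >= 2 and core.cs_centroid_mm is not None]
    for roi in case.roi_list:
        if _roi_cs_confirmed(case, roi):
            vox = np.argwhere(roi.mask.values) * np.asarray(case.grid.spacing_mm)
            pts.extend(vox)
    return pts


def _roi_cs_confirmed(case: PatientCase, roi: RoiMask) -> bool:
    return any(c.targeted and c.roi_id == roi.roi_id and c.isup_grade >= 2
               for c in case.cores)


def _hemisphere_contains(case: PatientCase, side: str,
                         points: list[np.ndarray]) -> bool:
    c = case.gland_centroid_mm()
    tol = 0.5 * max(case.grid.spacing_mm)
    if side == "left":      # x increases to patient-left
        return all(p[0] >= c[0] - tol for p in points)
    if side == "right":
        return all(p[0] <= c[0] + tol for p in points)
    if side == "anterior":  # y increases to anterior
        return all(p[1] >= c[1] - tol for p in points)
    raise ValueError(f"unknown hemisphere {side!r}")


def candidate_hemispheres(case: PatientCase) -> list[str]:
    """Hemispheres (left/right/anterior) containing all preoperative
    significant-cancer evidence; lateral sides listed before anterior."""
    pts = _cs_evidence_points(case)
    if not pts:
        return list(HEMISPHERES)
    return [s for s in HEMISPHERES if _hemisphere_contains(case, s, pts)]


def screen_focal_candidate(case: PatientCase) -> EligibilityResult:
    """Preoperative focal-therapy inclusion screen.

    1. At least one ROI harbours ISUP grade 2-3 cancer on a targeted core.
    2. All significant-cancer evidence (positive cores, confirmed ROIs) is
       confined to one lateral hemisphere or the anterior half.
    3. No prior radiation or ablative treatment.
    """
    if not case.cores:
        raise ValueError("case has no biopsy cores; screen requires biopsy data")
    c1 = any(
        c.targeted and c.isup_grade in (2, 3) for c in case.cores
    ) and any(_roi_cs_confirmed(case, roi) and any(
        c.targeted and c.roi_id == roi.roi_id and c.isup_grade in (2, 3)
        for c in case.cores) for roi in case.roi_list)
    c2 = len(candidate_hemispheres(case)) > 0
    c3 = not case.prior_treatment
    reasons = []
    if not c1:
        reasons.append("criterion 1: no ROI with a targeted core of ISUP grade 2-3")
    if not c2:
        reasons.append("criterion 2: significant cancer not confined to one "
                       "hemisphere or the anterior gland")
    if not c3:
        reasons.append("criterion 3: prior radiation or ablative treatment")
    return EligibilityResult(c1 and c2 and c3,
                             {"criterion1": c1, "criterion2": c2, "criterion3": c3},
                             reasons)


# --------------------------------------------------------------------------
# cohorts and manifests


def iter_cohort(config: PhantomConfig, n: int, seed: int,
                filtered: bool = False, id_prefix: str = "case",
                max_attempts_factor: int = 20) -> Iterator[PatientCase]:
    """Yield ``n`` cases one at a time (constant memory); optionally only
    cases passing the focal-therapy screen. ``id_prefix`` keeps case ids
    distinct across cohorts."""
    rng = np.random.default_rng(seed)
    emitted = 0
    attempts = 0
    while emitted < n:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise RuntimeError("cohort generation exceeded the attempt budget; "
                               "the eligibility screen may be too strict for "
                               "this configuration")
        case = sample_case(config, rng, case_id=f"{id_prefix}{attempts:05d}")
        if filtered and not screen_focal_candidate(case).eligible:
            continue
        emitted += 1
        yield case


def case_summary(case: PatientCase) -> dict:
    sats = sorted(lab for lab in case.lesion_grades if lab >= 2) \
        if case.lesion_grades else []
    return {
        "case_id": case.case_id,
        "psa_ng_ml": round(case.psa_ng_ml, 4),
        "slab": list(case.slab),
        "n_rois": len(case.roi_list),
        "n_cores": len(case.cores),
        "n_satellites": len(sats),
        "lesion_grades": {str(k): v for k, v in (case.lesion_grades or {}).items()},
        "truth_voxels": case.truth_cs.count,
        "gland_voxels": case.gland.count,
        "prior_treatment": case.prior_treatment,
        "cores": [
            {"id": c.core_id, "isup": c.isup_grade,
             "cancer_length_mm": round(c.cancer_length_mm, 3),
             "targeted": c.targeted}
            for c in case.cores
        ],
    }


def generate_cohort(config: PhantomConfig, n: int, seed: int,
                    filtered: bool = False,
                    id_prefix: str = "case") -> tuple[list[PatientCase], dict]:
    """Generate a cohort plus a reproducible JSON-serializable manifest.

    The manifest hash is a deterministic digest of the configuration, seed
    and per-case summaries: identical seeds give identical manifests.
    """
    cases = list(iter_cohort(config, n, seed, filtered=filtered,
                         id_prefix=id_prefix))
    manifest = {
        "seed": seed,
        "n": n,
        "filtered": filtered,
        "config": asdict(config),
        "cases": [case_summary(c) for c in cases],
    }
    manifest["hash"] = manifest_hash(manifest)
    return cases, manifest


def manifest_hash(manifest: dict) -> str:
    payload = {k: v for k, v in manifest.items() if k != "hash"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def cores_to_records(case: PatientCase) -> list[dict]:
    """One row per biopsy core, for CSV export."""
    rows = []
    for c in case.cores:
        rows.append({
            "case_id": case.case_id, "core_id": c.core_id,
            "entry_x_mm": c.entry_mm[0], "entry_y_mm": c.entry_mm[1],
            "entry_z_mm": c.entry_mm[2],
            "tip_x_mm": c.tip_mm[0], "tip_y_mm": c.tip_mm[1],
            "tip_z_mm": c.tip_mm[2],
            "isup_grade": c.isup_grade,
            "cancer_length_mm": c.cancer_length_mm,
            "targeted": c.targeted, "roi_id": c.roi_id or "",
        })
    return rows
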