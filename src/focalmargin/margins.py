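"""Treatment-margin construction.

Four margin families are supported:

* ``cem_threshold`` — superlevel set of the cancer estimation map at a
  threshold t, smoothed by Gaussian-blur-and-rethreshold;
* ``roi`` — the raw MRI region(s) of interest with biopsy-confirmed
  significant cancer;
* ``roi_expanded`` — a uniform Euclidean expansion (default 10 mm) of
  those ROIs;
* ``hemigland`` — the left, right or anterior prostate hemisphere chosen
  to contain all preoperative significant-cancer evidence.

All margins are clipped to the gland by default, because margin volume is
reported as a percent of the prostate. Gaussian blur is order-preserving,
so smoothed threshold margins inherit the nesting of the raw superlevel
sets: higher thresholds always give smaller margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PatientCase, candidate_hemispheres
from .voxelgeom import Mask, distance_map

DEFAULT_SMOOTHING_MM = 2.0
DEFAULT_EXPANSION_MM = 10.0


@dataclass
class MarginMask:
    """A binary treatment margin together with the recipe that produced it."""

    mask: Mask
    recipe: dict

    @property
    def kind(self) -> str:
        return self.recipe["kind"]

    def save(self, path) -> None:
        """Write the margin as a NIfTI mask with a JSON recipe sidecar."""
        import json
        from pathlib import Path
        from .io import write_mask
        path = Path(path)
        write_mask(path, self.mask)
        sidecar = path.parent / (path.name.split(".")[0] + ".recipe.json")
        sidecar.write_text(json.dumps(self.recipe, indent=2, default=str))


def _smooth_binary(values: np.ndarray, smoothing_mm: float,
                   spacing_mm) -> np.ndarray:
    """Gaussian blur of the indicator, re-thresholded at 0.5.

    Monotone in the input set, so nesting of inputs is preserved.
    """
    if smoothing_mm <= 0:
        return values.copy()
    sigma = smoothing_mm / np.asarray(spacing_mm)
    blurred = ndimage.gaussian_filter(values.astype(np.float32), sigma=sigma)
    return blurred >= 0.5


def _extended_cem(case: PatientCase) -> np.ndarray:
    """CEM with exterior voxels filled by their nearest gland voxel's value.

    The CEM is only defined on gland voxels, so blurring a raw superlevel
    set against a zero exterior would erode margins wherever cancer risk
    reaches the capsule. Thresholding this nearest-neighbor extension
    instead lets the set continue across the boundary; the final margin is
    clipped back to the gland. The extension is monotone, so threshold
    nesting is preserved. Cached per case (the extension only depends on
    the attached CEM and the gland).
    """
    cache = getattr(case, "_cem_ext_cache", None)
    if cache is not None and cache[0] is case.cem:
        return cache[1]
    _, nearest = ndimage.distance_transform_edt(
        ~case.gland.values, sampling=case.grid.spacing_mm, return_indices=True)
    ext = case.cem.copy()
    outside = ~case.gland.values
    ext[outside] = ext[tuple(nearest[:, outside])]
    case._cem_ext_cache = (case.cem, ext)
    return ext


def threshold_margin(case: PatientCase, t: float,
                     smoothing_mm: float = DEFAULT_SMOOTHING_MM) -> MarginMask:
    """Margin from the CEM superlevel set {cem >= t}, smoothed and clipped
    to the gland."""
    if case.cem is None:
        raise ValueError("case has no CEM attached")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    raw = _extended_cem(case) >= t
    values = _smooth_binary(raw, smoothing_mm, case.grid.spacing_mm)
    values &= case.gland.values
    return MarginMask(Mask(case.grid, values),
                      {"kind": "cem_threshold", "threshold": float(t),
                       "smoothing_mm": float(smoothing_mm)})


def raw_superlevel(case: PatientCase, t: float) -> Mask:
    """Unsmoothed superlevel set {cem >= t} clipped to the gland (used for
    exact nesting assertions)."""
    if case.cem is None:
        raise ValueError("case has no CEM attached")
    return Mask(case.grid, (case.cem >= t) & case.gland.values)


def margin_sweep(case: PatientCase, thresholds,
                 smoothing_mm: float = DEFAULT_SMOOTHING_MM) -> list[MarginMask]:
    """One margin per threshold; thresholds must be ascending in [0, 1]."""
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or thr.size == 0:
        raise ValueError("thresholds must be a nonempty 1D sequence")
    if np.any(np.diff(thr) < 0):
        raise ValueError("thresholds must be ascending")
    if thr[0] < 0 or thr[-1] > 1:
        raise ValueError("thresholds must lie in [0, 1]")
    return [threshold_margin(case, float(t), smoothing_mm) for t in thr]


def csPCa_roi_union(case: PatientCase) -> Mask:
    """Union of ROIs with a targeted core showing significant cancer."""
    from .phantom import _roi_cs_confirmed
    values = np.zeros(case.grid.shape, dtype=bool)
    for roi in case.roi_list:
        if _roi_cs_confirmed(case, roi):
            values |= roi.mask.values
    return Mask(case.grid, values)


def roi_margin(case: PatientCase) -> MarginMask:
    """The biopsy-confirmed ROI(s) themselves, with no added margin."""
    union = csPCa_roi_union(case)
    if union.is_empty:
        raise ValueError("no biopsy-confirmed ROI in this case")
    return MarginMask(union, {"kind": "roi"})


def expand_roi(roi_union: Mask, r_mm: float, gland: Mask,
               clip_to_gland: bool = True) -> MarginMask:
    """Uniform expansion: voxels whose center lies within ``r_mm`` of the
    ROI (closed ball; boundary ties included)."""
    if r_mm < 0:
        raise ValueError("expansion radius must be >= 0")
    if roi_union.is_empty:
        raise ValueError("empty ROI union")
    values = distance_map(roi_union) <= r_mm
    if clip_to_gland:
        values &= gland.values
    return MarginMask(Mask(roi_union.grid, values),
                      {"kind": "roi_expanded", "r_mm": float(r_mm),
                       "clipped": bool(clip_to_gland)})


def expanded_roi_margin(case: PatientCase,
                        r_mm: float = DEFAULT_EXPANSION_MM,
                        clip_to_gland: bool = True) -> MarginMask:
    return expand_roi(csPCa_roi_union(case), r_mm, case.gland,
                      clip_to_gland=clip_to_gland)


def hemigland_margin(case: PatientCase) -> MarginMask:
    """Hemigland margin: the gland half (sagittal split for left/right,
    coronal split for anterior, both through the gland centroid) containing
    all preoperative significant-cancer evidence.

    Ties prefer a lateral hemisphere over the anterior one. Raises if no
    single hemisphere contains all the evidence.
    """
    sides = candidate_hemispheres(case)
    if not sides:
        raise ValueError("not a hemigland candidate: significant cancer is "
                         "not confined to one hemisphere or the anterior gland")
    side = sides[0]  # candidate_hemispheres lists lateral sides first
    c = case.gland_centroid_mm()
    spacing = np.asarray(case.grid.spacing_mm)
    values = np.zeros(case.grid.shape, dtype=bool)
    if side in ("left", "right"):
        xs = np.arange(case.grid.shape[0]) * spacing[0]
        sel = xs >= c[0] if side == "left" else xs <= c[0]
        values[sel, :, :] = True
    else:
        ys = np.arange(case.grid.shape[1]) * spacing[1]
        values[:, ys >= c[1], :] = True
    values &= case.gland.values
    return MarginMask(Mask(case.grid, values),
                      {"kind": "hemigland", "side": side})
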