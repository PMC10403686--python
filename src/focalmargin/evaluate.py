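"""Geometric margin evaluation, lesion decomposition and cohort reporting.

All voxel-level metrics are restricted to gland voxels whose z index lies
within the apex-to-base analysis slab, emulating the region where
whole-mount ground truth is known. ``extent_missed_mm`` is the maximum
Euclidean distance of any missed significant-cancer voxel from the margin
set — the penetration depth of cancer beyond the margin (a mean over
missed voxels is also reported as a secondary figure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ecs import ECSLookup, encapsulation_critical_index
from .margins import MarginMask
from .phantom import PatientCase
from .voxelgeom import Mask, components, distance_map, volume_fraction


@dataclass
class LesionDecomposition:
    """Index lesion and satellites of a significant-cancer mask.

    Components closer than ``merge_distance_mm`` to the index are absorbed
    into it; the remainder are satellites, each at least that distance away.
    """

    index: Mask
    satellites: list[Mask]
    merged_labels: list[int]
    merge_distance_mm: float = 2.0


@dataclass
class CaseMetrics:
    sensitivity: float
    specificity: float
    volume_fraction: float
    extent_missed_mm: float
    extent_missed_mean_mm: float
    negative_margin_all: bool
    negative_margin_index: bool
    failure_attribution: str  # none | index_extension | satellite | both
    evaluable: bool = True
    empty_margin: bool = False


@dataclass
class CalibrationReport:
    thresholds: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    n: int
    slope: float
    intercept: float
    r_squared: float
    median_abs_error: float
    iqr_abs_error: tuple[float, float]
    ks_statistic: float
    ks_pvalue: float


def surface_distance_mm(reference_values: np.ndarray, other_values: np.ndarray,
                        spacing_mm) -> float:
    """Minimum surface-to-surface distance between two voxel sets.

    Voxels are axis-aligned boxes of size ``spacing_mm`` centred on the
    lattice; the center-to-center distance is reduced by each box's extent
    along the connecting direction (the box support function), so two boxes
    separated by one empty 1-mm voxel are 1 mm apart, not 2.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    a = np.argwhere(reference_values) * spacing
    b = np.argwhere(other_values) * spacing
    if a.size == 0 or b.size == 0:
        raise ValueError("surface distance of an empty set is undefined")
    best = np.inf
    for chunk in np.array_split(b, max(1, len(b) // 256)):
        diff = a[None, :, :] - chunk[:, None, :]
        d = np.linalg.norm(diff, axis=2)
        d_safe = np.where(d == 0, 1.0, d)
        support = np.abs(diff / d_safe[..., None]) @ spacing
        best = min(best, float(np.maximum(d - support, 0.0).min()))
    return best


def decompose_lesions(truth_cs: Mask, merge_distance_mm: float = 2.0,
                      connectivity: int = 26) -> LesionDecomposition:
    """Split significant cancer into an index lesion and satellites.

    The index is the largest-volume connected region; any other region
    whose surface lies closer than ``merge_distance_mm`` to the index is
    merged into it (repeatedly, until stable — a merged component can pull
    further components in). Remaining regions are satellites.
    """
    if truth_cs.is_empty:
        raise ValueError("empty significant-cancer mask")
    regions = components(truth_cs, connectivity=connectivity)
    index = regions.region_mask(1)
    others = list(range(2, regions.n_regions + 1))
    merged: list[int] = []
    changed = True
    while changed and others:
        changed = False
        still = []
        for lab in others:
            vox = regions.labels == lab
            gap = surface_distance_mm(index.values, vox, index.grid.spacing_mm)
            if gap < merge_distance_mm:
                index = Mask(index.grid, index.values | vox)
                merged.append(lab)
                changed = True
            else:
                still.append(lab)
        others = still
    satellites = [regions.region_mask(lab) for lab in others]
    return LesionDecomposition(index, satellites, merged, merge_distance_mm)


def _slab_restrict(case: PatientCase, values: np.ndarray) -> np.ndarray:
    out = values.copy()
    z0, z1 = case.slab
    out[:, :, :z0] = False
    out[:, :, z1 + 1:] = False
    return out


def case_metrics(margin: MarginMask, case: PatientCase,
                 decomposition: Optional[LesionDecomposition] = None
                 ) -> CaseMetrics:
    """Slab-restricted voxel metrics of one margin against ground truth."""
    if margin.mask.grid != case.grid:
        raise ValueError("margin and case grids differ")
    gland = _slab_restrict(case, case.gland.values)
    truth = _slab_restrict(case, case.truth_cs.values) & gland
    marg = margin.mask.values & gland
    if not truth.any():
        return CaseMetrics(np.nan, np.nan, np.nan, np.nan, np.nan,
                           False, False, "none", evaluable=False)

    n_truth = truth.sum()
    tp = (marg & truth).sum()
    benign = gland & ~truth
    tn = (benign & ~marg).sum()
    sensitivity = tp / n_truth
    specificity = tn / benign.sum() if benign.any() else np.nan
    vol_frac = volume_fraction(margin.mask, case.gland)

    missed = truth & ~marg
    empty_margin = not margin.mask.values.any()
    if not missed.any():
        extent = extent_mean = 0.0
    elif empty_margin:
        # no margin surface exists: report penetration relative to the
        # gland boundary (distance of missed cancer from the gland exterior)
        dmap = ndimage.distance_transform_edt(case.gland.values,
                                              sampling=case.grid.spacing_mm)
        extent = float(dmap[missed].max())
        extent_mean = float(dmap[missed].mean())
    else:
        dmap = distance_map(margin.mask)
        extent = float(dmap[missed].max())
        extent_mean = float(dmap[missed].mean())

    if decomposition is None:
        decomposition = decompose_lesions(case.truth_cs)
    index_slab = _slab_restrict(case, decomposition.index.values) & gland
    neg_all = not missed.any()
    neg_index = bool(np.all(marg[index_slab])) if index_slab.any() else True

    attribution = "none"
    if missed.any():
        in_index = (missed & decomposition.index.values).any()
        in_sat = any((missed & s.values).any() for s in decomposition.satellites)
        attribution = ("both" if in_index and in_sat
                       else "index_extension" if in_index
                       else "satellite" if in_sat else "none")
    return CaseMetrics(float(sensitivity), float(specificity), float(vol_frac),
                       extent, extent_mean, bool(neg_all), bool(neg_index),
                       attribution, evaluable=True, empty_margin=empty_margin)


# --------------------------------------------------------------------------
# cohort comparison table


def _paired_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    diffs = np.asarray(a) - np.asarray(b)
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size == 0 or np.allclose(diffs, 0.0):
        return 1.0  # no paired differences
    return float(stats.wilcoxon(diffs).pvalue)


def _rate_chi_square(k1: int, n1: int, k2: int, n2: int) -> float:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0  # degenerate table: identical margins or empty rows
    return float(stats.chi2_contingency(table).pvalue)


def _iqr(x: np.ndarray) -> tuple[float, float]:
    x = x[~np.isnan(x)]
    if x.size == 0:
        return (np.nan, np.nan)
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def cohort_table(cohort: Sequence[PatientCase],
                 recipes: dict[str, Callable[[PatientCase], MarginMask]],
                 reference: str = "default_ai") -> pd.DataFrame:
    """Cohort comparison of margin recipes (one row per recipe).

    ``recipes`` maps a row name to a callable producing a margin for a
    case; a callable may raise ``ValueError`` for inapplicable cases
    (e.g. hemigland margins for non-candidates), which shrinks that row's
    denominator. Continuous metrics are compared against the ``reference``
    row with Wilcoxon signed-rank tests on the paired subset; negative
    margin rates with chi-square tests.
    """
    per_recipe: dict[str, dict[str, CaseMetrics]] = {}
    for name, fn in recipes.items():
        row: dict[str, CaseMetrics] = {}
        for case in cohort:
            try:
                m = fn(case)
            except ValueError:
                continue
            cm = case_metrics(m, case)
            if cm.evaluable:
                row[case.case_id] = cm
        if not row:
            warnings.warn(f"margin recipe {name!r} applicable to no case; "
                          "row omitted")
            continue
        per_recipe[name] = row

    if reference not in per_recipe:
        raise ValueError(f"reference recipe {reference!r} produced no rows")
    ref = per_recipe[reference]

    rows = []
    for name, row in per_recipe.items():
        ids = sorted(row)
        sens = np.array([row[i].sensitivity for i in ids])
        spec = np.array([row[i].specificity for i in ids])
        ext = np.array([row[i].extent_missed_mm for i in ids])
        vol = np.array([row[i].volume_fraction for i in ids])
        neg_all = np.array([row[i].negative_margin_all for i in ids])
        neg_idx = np.array([row[i].negative_margin_index for i in ids])

        paired = sorted(set(ids) & set(ref))
        pair = {
            metric: (np.array([getattr(row[i], metric) for i in paired]),
                     np.array([getattr(ref[i], metric) for i in paired]))
            for metric in ("sensitivity", "specificity", "extent_missed_mm",
                           "volume_fraction")
        }
        ref_ids = sorted(ref)
        ref_neg_all = np.array([ref[i].negative_margin_all for i in ref_ids])
        ref_neg_idx = np.array([ref[i].negative_margin_index for i in ref_ids])

        rows.append({
            "margin": name,
            "n": len(ids),
            "sensitivity_mean": float(np.nanmean(sens)),
            "sensitivity_iqr": _iqr(sens),
            "sensitivity_p_vs_ref": _paired_signed_rank(*pair["sensitivity"]),
            "specificity_mean": float(np.nanmean(spec)),
            "specificity_iqr": _iqr(spec),
            "specificity_p_vs_ref": _paired_signed_rank(*pair["specificity"]),
            "extent_missed_mean_mm": float(np.nanmean(ext)),
            "extent_missed_iqr_mm": _iqr(ext),
            "extent_missed_p_vs_ref": _paired_signed_rank(*pair["extent_missed_mm"]),
            "volume_fraction_mean": float(np.nanmean(vol)),
            "volume_fraction_iqr": _iqr(vol),
            "volume_fraction_p_vs_ref": _paired_signed_rank(*pair["volume_fraction"]),
            "negative_margin_any_count": int(neg_all.sum()),
            "negative_margin_any_rate": float(neg_all.mean()),
            "negative_margin_any_p_vs_ref": _rate_chi_square(
                int(neg_all.sum()), len(ids),
                int(ref_neg_all.sum()), len(ref_ids)),
            "negative_margin_index_count": int(neg_idx.sum()),
            "negative_margin_index_rate": float(neg_idx.mean()),
            "negative_margin_index_p_vs_ref": _rate_chi_square(
                int(neg_idx.sum()), len(ids),
                int(ref_neg_idx.sum()), len(ref_ids)),
        })
    return pd.DataFrame(rows).set_index("margin")


# --------------------------------------------------------------------------
# ECS calibration-curve assessment


def calibration_curve(lookup: ECSLookup,
                      test_cohort: Iterable[PatientCase],
                      calibration_ids: Optional[set] = None,
                      allow_overlap: bool = False) -> CalibrationReport:
    """Predicted-versus-observed negative-margin rates across the threshold
    grid on an independent test cohort.

    ``calibration_ids`` (case ids of the calibration cohort) lets the
    overlap precondition be checked; duplicated cohorts are rejected unless
    ``allow_overlap=True`` (test-harness use only).
    """
    thresholds = lookup.thresholds
    crit = []
    n = 0
    for case in test_cohort:
        if calibration_ids and case.case_id in calibration_ids and not allow_overlap:
            raise ValueError(
                f"case {case.case_id} appears in both calibration and test "
                "cohorts")
        crit.append(encapsulation_critical_index(case, thresholds,
                                                 lookup.smoothing_mm))
        n += 1
    if n == 0:
        raise ValueError("empty test cohort")
    crit = np.asarray(crit)
    observed = np.array([(crit >= i).mean() for i in range(len(thresholds))])
    predicted = lookup.ecs

    abs_err = np.abs(predicted - observed)
    med = float(np.median(abs_err))
    iqr = _iqr(abs_err)
    if np.ptp(predicted) == 0:
        warnings.warn("degenerate lookup: predicted rates are constant; "
                      "regression undefined")
        slope = intercept = r2 = float("nan")
    else:
        res = stats.linregress(predicted, observed)
        slope, intercept, r2 = float(res.slope), float(res.intercept), \
            float(res.rvalue ** 2)
    ks = stats.ks_2samp(predicted, observed)
    return CalibrationReport(thresholds.copy(), predicted.copy(), observed,
                             n, slope, intercept, r2, med, iqr,
                             float(ks.statistic), float(ks.pvalue))
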