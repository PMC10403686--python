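"""Encapsulation confidence score (ECS) calibration and default-margin selection.

The ECS maps a CEM threshold to the calibrated probability that the margin
produced at that threshold fully encapsulates all clinically significant
cancer (a *negative margin*). It is estimated over a calibration cohort as
the proportion of cases whose margin at each threshold covers every
significant-cancer voxel within the apex-to-base analysis slab, then made
monotone nonincreasing by a cumulative minimum over ascending thresholds.

Because Gaussian-blur smoothing preserves the nesting of superlevel sets,
encapsulation is monotone in the threshold per case: a margin is negative
for all thresholds up to a case-specific critical threshold. Calibration
therefore reduces to locating that critical grid index per case (binary
search), which the cohort-level proportions are then read off from. A
direct per-threshold recount gives identical proportions and serves as the
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .margins import DEFAULT_SMOOTHING_MM, MarginMask, threshold_margin
from .phantom import PatientCase
from .voxelgeom import Mask, volume_fraction

DEFAULT_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 10)


@dataclass
class ECSLookup:
    """Monotone lookup from CEM threshold to negative-margin probability."""

    thresholds: np.ndarray
    ecs: np.ndarray
    n_cases: int
    smoothing_mm: float = DEFAULT_SMOOTHING_MM
    enforcement_deltas: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.ecs = np.asarray(self.ecs, dtype=float)
        if self.thresholds.shape != self.ecs.shape:
            raise ValueError("thresholds and ecs must have equal length")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if np.any(np.diff(self.ecs) > 1e-12):
            raise ValueError("ecs must be nonincreasing in the threshold")
        if self.ecs.min() < 0 or self.ecs.max() > 1:
            raise ValueError("ecs values must lie in [0, 1]")
        if self.enforcement_deltas is None:
            self.enforcement_deltas = np.zeros_like(self.ecs)

    def value_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - t)))
        if not np.isclose(self.thresholds[i], t):
            raise KeyError(f"threshold {t} is not on the lookup grid")
        return float(self.ecs[i])

    def save(self, path) -> None:
        """Serialize as CSV (threshold, ecs, n_cases) + JSON metadata."""
        import json
        from pathlib import Path
        import pandas as pd
        path = Path(path)
        pd.DataFrame({"threshold": self.thresholds, "ecs": self.ecs,
                      "n_cases": self.n_cases}).to_csv(path, index=False)
        meta = path.parent / (path.name.split(".")[0] + ".meta.json")
        meta.write_text(json.dumps({
            "n_cases": self.n_cases, "smoothing_mm": self.smoothing_mm,
            "enforcement_deltas": self.enforcement_deltas.tolist(),
        }, indent=2))

    @classmethod
    def load(cls, path) -> "ECSLookup":
        import json
        from pathlib import Path
        import pandas as pd
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.parent / (path.name.split(".")[0] + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df["threshold"].to_numpy(), df["ecs"].to_numpy(),
                   n_cases=int(df["n_cases"].iloc[0]),
                   smoothing_mm=float(meta.get("smoothing_mm",
                                               DEFAULT_SMOOTHING_MM)),
                   enforcement_deltas=np.asarray(
                       meta.get("enforcement_deltas")) if meta else None)


@dataclass
class ECSVolumeCurve:
    """Per-threshold (margin volume fraction, ECS) pairs and the selected
    default threshold t*."""

    thresholds: np.ndarray
    volume_fractions: np.ndarray
    ecs: np.ndarray
    t_star: float
    t_star_index: int
    objective: np.ndarray


def _slab_truth_indices(case: PatientCase) -> tuple[np.ndarray, ...]:
    truth = case.truth_cs.values.copy()
    z0, z1 = case.slab
    truth[:, :, :z0] = False
    truth[:, :, z1 + 1:] = False
    return np.nonzero(truth)


def margin_is_negative(margin: MarginMask, case: PatientCase) -> bool:
    """True iff every slab-restricted significant-cancer voxel lies inside
    the margin."""
    idx = _slab_truth_indices(case)
    if idx[0].size == 0:
        return True  # vacuous: no adjudicable cancer in the slab
    return bool(np.all(margin.mask.values[idx]))


def encapsulation_critical_index(case: PatientCase, thresholds=DEFAULT_THRESHOLDS,
                                 smoothing_mm: float = DEFAULT_SMOOTHING_MM) -> int:
    """Largest grid index whose margin is negative for this case (-1 if none).

    Relies on margin nesting in the threshold; validated against a direct
    per-threshold scan in the test suite.
    """
    if case.cem is None:
        raise ValueError("case has no CEM attached")
    thresholds = np.asarray(thresholds, dtype=float)
    idx = _slab_truth_indices(case)

    def negative(i: int) -> bool:
        m = threshold_margin(case, float(thresholds[i]), smoothing_mm)
        return idx[0].size == 0 or bool(np.all(m.mask.values[idx]))

    lo, hi = 0, len(thresholds) - 1
    if not negative(lo):
        return -1
    if negative(hi):
        return hi
    # invariant: negative(lo), not negative(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if negative(mid):
            lo = mid
        else:
            hi = mid
    return lo


def calibrate_ecs(cohort: Iterable[PatientCase], thresholds=DEFAULT_THRESHOLDS,
                  smoothing_mm: float = DEFAULT_SMOOTHING_MM) -> ECSLookup:
    """Proportion of cohort cases with negative margins at each threshold,
    with monotonicity enforced by cumulative minimum.

    Accepts any iterable (including a generator) so large cohorts need not
    be held in memory.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    crit = [encapsulation_critical_index(c, thresholds, smoothing_mm)
            for c in cohort]
    n = len(crit)
    if n == 0:
        raise ValueError("empty calibration cohort")
    crit = np.asarray(crit)
    raw = np.array([(crit >= i).mean() for i in range(len(thresholds))])
    enforced = np.minimum.accumulate(raw)
    return ECSLookup(thresholds, enforced, n_cases=n, smoothing_mm=smoothing_mm,
                     enforcement_deltas=raw - enforced)


def ecs_volume_curve(lookup: ECSLookup, case: PatientCase,
                     volume_weight: float = 1.0) -> ECSVolumeCurve:
    """ECS-versus-margin-volume curve and the default threshold t*.

    t* maximizes ECS(t) - volume_weight * volume_fraction(t), both terms on
    the [0, 1] scale; ties break toward the larger threshold (smaller margin).
    """
    if case.cem is None:
        raise ValueError("case has no CEM attached")
    fracs = np.empty_like(lookup.thresholds)
    for i, t in enumerate(lookup.thresholds):
        m = threshold_margin(case, float(t), lookup.smoothing_mm)
        fracs[i] = volume_fraction(m.mask, case.gland)
    objective = lookup.ecs - volume_weight * fracs
    # argmax with ties toward larger t: scan reversed
    best = len(objective) - 1 - int(np.argmax(objective[::-1]))
    return ECSVolumeCurve(lookup.thresholds.copy(), fracs, lookup.ecs.copy(),
                          t_star=float(lookup.thresholds[best]),
                          t_star_index=best, objective=objective)


def default_margin(lookup: ECSLookup, case: PatientCase,
                   volume_weight: float = 1.0
                   ) -> tuple[MarginMask, float, ECSVolumeCurve]:
    """Patient-specific default margin at t*, with its predicted
    negative-margin probability ECS(t*).

    Returns (margin, predicted_ecs, curve). An empty selected margin is
    flagged in the recipe (``empty_default_margin``) rather than raised.
    """
    curve = ecs_volume_curve(lookup, case, volume_weight=volume_weight)
    margin = threshold_margin(case, curve.t_star, lookup.smoothing_mm)
    margin.recipe["kind"] = "default_ai"
    margin.recipe["empty_default_margin"] = bool(margin.mask.is_empty)
    predicted = float(lookup.ecs[curve.t_star_index])
    return margin, predicted, curve
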