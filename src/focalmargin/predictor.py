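"""Stand-in voxel-wise cancer-probability model.

The production model this mirrors combines a 3D convolutional image branch
with engineered features classified by gradient-boosted trees, averaged
over five cross-validation folds. Phantoms carry no MRI intensities, so
the stand-in uses only the engineered feature classes — spatial
relationships between the sample point and the biopsy cores, the ROIs and
the prostate capsule, plus serum PSA — and keeps the fold-ensemble
structure: the prediction is the mean of the fold models' probabilities.

This is a fidelity limitation by design: the stand-in exercises the
margin-planning pipeline downstream of the probability map, it does not
reproduce the original model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.ensemble import HistGradientBoostingClassifier

from .io import read_volume
from .phantom import PatientCase

DEFAULT_K_CORES = 3

FEATURE_NAMES_BASE = ["capsule_depth_mm", "roi_distance_mm", "roi_pirads",
                      "psa_ng_ml"]


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Euclidean distance (mm) from each point to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def feature_names(k_cores: int = DEFAULT_K_CORES) -> list[str]:
    names = list(FEATURE_NAMES_BASE)
    for i in range(k_cores):
        names += [f"core{i}_distance_mm", f"core{i}_isup",
                  f"core{i}_cancer_length_mm", f"core{i}_targeted"]
    return names


def engineer_features(case: PatientCase, points_mm: np.ndarray,
                      k_cores: int = DEFAULT_K_CORES) -> np.ndarray:
    """Feature matrix for sample points (mm coordinates, inside the gland).

    Columns: signed capsule depth (inward-positive, 0 on the capsule
    surface), distance to the nearest ROI and that ROI's suspicion score,
    PSA, then for each of the k nearest cores: point-to-segment distance,
    ISUP grade, cancer length and the targeted flag.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    spacing = np.asarray(case.grid.spacing_mm)
    idx = np.round(points_mm / spacing).astype(int)
    shape = np.asarray(case.grid.shape)
    inside_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inside_grid.all() or not np.all(case.gland.values[tuple(idx.T)]):
        raise ValueError("all sample points must lie inside the gland")

    # capsule depth: exact point distance to the nearest exterior voxel
    # center, shifted half a voxel so the capsule surface sits at depth 0
    depth, ext_idx = ndimage.distance_transform_edt(
        case.gland.values, sampling=spacing, return_indices=True)
    nearest_ext = ext_idx[:, idx[:, 0], idx[:, 1], idx[:, 2]].T * spacing
    capsule = np.linalg.norm(points_mm - nearest_ext, axis=1) - 0.5 * spacing.min()
    capsule = np.maximum(capsule, 0.0)

    # nearest ROI distance and score
    n = len(points_mm)
    roi_dist = np.full(n, np.inf)
    roi_score = np.zeros(n)
    for roi in case.roi_list:
        d = ndimage.distance_transform_edt(~roi.mask.values, sampling=spacing)
        dv = d[tuple(idx.T)]
        closer = dv < roi_dist
        roi_dist[closer] = dv[closer]
        roi_score[closer] = roi.pirads
    if np.isinf(roi_dist).any():
        roi_dist[np.isinf(roi_dist)] = depth.max() + 10.0

    cols = [capsule, roi_dist, roi_score, np.full(n, case.psa_ng_ml)]

    dists = np.stack([
        _point_segment_distance(points_mm, np.asarray(c.entry_mm),
                                np.asarray(c.tip_mm))
        for c in case.cores
    ], axis=1)  # (n, n_cores)
    order = np.argsort(dists, axis=1)[:, :k_cores]
    rows = np.arange(n)[:, None]
    grades = np.asarray([c.isup_grade for c in case.cores], dtype=float)
    lengths = np.asarray([c.cancer_length_mm for c in case.cores])
    targeted = np.asarray([float(c.targeted) for c in case.cores])
    for j in range(k_cores):
        sel = order[:, min(j, order.shape[1] - 1)]
        cols += [dists[rows[:, 0], sel], grades[sel], lengths[sel],
                 targeted[sel]]
    return np.column_stack(cols)


@dataclass
class StandInModel:
    """Fold-ensemble probabilistic classifier over engineered features."""

    fold_models: list
    k_cores: int = DEFAULT_K_CORES
    seed: int = 0
    config_hash: str = ""

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        preds = [m.predict_proba(features)[:, 1] for m in self.fold_models]
        return np.mean(preds, axis=0)

    def save(self, path) -> None:
        """Serialize the model artifact (fold models, seed, config hash)."""
        import pickle
        from pathlib import Path
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path) -> "StandInModel":
        import pickle
        from pathlib import Path
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a StandInModel")
        return model


def _training_samples(case: PatientCase, rng,
                      per_case: int, k_cores: int):
    """Balanced 1:1 positive:negative voxel subsample inside the gland."""
    spacing = np.asarray(case.grid.spacing_mm)
    pos_idx = np.argwhere(case.truth_cs.values)
    neg_idx = np.argwhere(case.gland.values & ~case.truth_cs.values)
    m = min(per_case // 2, len(pos_idx), len(neg_idx))
    if m == 0:
        return None, None
    pos = pos_idx[rng.choice(len(pos_idx), m, replace=False)]
    neg = neg_idx[rng.choice(len(neg_idx), m, replace=False)]
    pts = np.vstack([pos, neg]) * spacing
    labels = np.r_[np.ones(m), np.zeros(m)]
    return engineer_features(case, pts, k_cores=k_cores), labels


def fit_standin(cohort: Sequence[PatientCase], folds: int = 5, seed: int = 0,
                samples_per_case: int = 400,
                k_cores: int = DEFAULT_K_CORES) -> StandInModel:
    """Fit the fold ensemble: cases are split into ``folds`` groups and each
    fold model is trained on the complement of one group.

    Raises ``ValueError("degenerate labels")`` if the pooled training
    labels contain a single class.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(cohort) < folds:
        raise ValueError("cohort smaller than the number of folds")
    rng = np.random.default_rng(seed)
    per_case = []
    for case in cohort:
        X, y = _training_samples(case, rng, samples_per_case, k_cores)
        per_case.append((X, y))
    valid = [y for _, y in per_case if y is not None]
    if not valid:
        raise ValueError("degenerate labels")
    ys = np.concatenate(valid)
    if len(np.unique(ys)) < 2:
        raise ValueError("degenerate labels")

    assignment = np.arange(len(cohort)) % folds
    rng.shuffle(assignment)
    fold_models = []
    for f in range(folds):
        keep = [i for i in range(len(cohort))
                if assignment[i] != f and per_case[i][0] is not None]
        X = np.vstack([per_case[i][0] for i in keep])
        y = np.concatenate([per_case[i][1] for i in keep])
        clf = HistGradientBoostingClassifier(
            max_iter=150, learning_rate=0.1, max_depth=4,
            random_state=int(seed + f),
        )
        clf.fit(X, y)
        fold_models.append(clf)
    import hashlib
    cfg_hash = hashlib.sha256(
        f"{folds}:{seed}:{samples_per_case}:{k_cores}".encode()).hexdigest()
    return StandInModel(fold_models, k_cores=k_cores, seed=seed,
                        config_hash=cfg_hash)


def predict_cem(model: StandInModel, case: PatientCase,
                attach: bool = True) -> np.ndarray:
    """Predict the voxel-wise cancer probability map for a case.

    Values lie in [0, 1] on gland voxels and are exactly 0 outside the
    gland; the map is attached to the case unless ``attach=False``.
    """
    spacing = np.asarray(case.grid.spacing_mm)
    idx = np.argwhere(case.gland.values)
    feats = engineer_features(case, idx * spacing, k_cores=model.k_cores)
    probs = model.predict_proba(feats)
    cem = np.zeros(case.grid.shape, dtype=np.float32)
    cem[tuple(idx.T)] = np.clip(probs, 0.0, 1.0 - 1e-6)
    if attach:
        case.attach_cem(cem)
    return cem


def load_external_cem(path, case: PatientCase, attach: bool = True) -> np.ndarray:
    """Load an externally produced CEM (NIfTI) and validate it against the
    case grid: shapes and spacings must match and values must lie in [0, 1]."""
    data, grid = read_volume(path)
    if grid != case.grid:
        raise ValueError(
            f"CEM grid {grid} does not match case grid {case.grid}")
    data = np.asarray(data, dtype=np.float32)
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise ValueError("CEM values must lie in [0, 1]")
    if attach:
        case.attach_cem(data)
    return data
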