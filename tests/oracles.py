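"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, BFS flood
fill, pairwise distances) and shares no code with the package internals.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial.distance import cdist


def voxel_centers_mm(shape, spacing):
    idx = np.indices(shape).reshape(3, -1).T
    return idx * np.asarray(spacing), idx


def brute_distance_map(values: np.ndarray, spacing) -> np.ndarray:
    """Min-over-mask-voxels Euclidean distance at every voxel center."""
    pts, _ = voxel_centers_mm(values.shape, spacing)
    mask_pts = np.argwhere(values) * np.asarray(spacing)
    d = cdist(pts, mask_pts).min(axis=1)
    return d.reshape(values.shape)


_OFFSETS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(values: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labels (arbitrary label order)."""
    labels = np.zeros(values.shape, dtype=int)
    next_label = 0
    offsets = _OFFSETS[connectivity]
    for start in map(tuple, np.argwhere(values)):
        if labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(nb, values.shape)) \
                        and values[nb] and not labels[nb]:
                    labels[nb] = next_label
                    queue.append(nb)
    return labels


def brute_set_distance(a_values, b_values, spacing) -> float:
    """Min pairwise distance between voxel centers of two sets."""
    a = np.argwhere(a_values) * np.asarray(spacing)
    b = np.argwhere(b_values) * np.asarray(spacing)
    return float(cdist(a, b).min())


def brute_surface_distance(a_values, b_values, spacing) -> float:
    """Min surface-to-surface distance between two sets of voxel boxes,
    by exhaustive pairwise enumeration (box support-function correction)."""
    spacing = np.asarray(spacing, dtype=float)
    a = np.argwhere(a_values) * spacing
    b = np.argwhere(b_values) * spacing
    best = np.inf
    for pa in a:
        diff = b - pa
        d = np.linalg.norm(diff, axis=1)
        d_safe = np.where(d == 0, 1.0, d)
        support = np.abs(diff / d_safe[:, None]) @ spacing
        best = min(best, float(np.maximum(d - support, 0.0).min()))
    return best


def brute_extent_missed(truth_values, margin_values, spacing) -> float:
    """Max over missed truth voxels of min distance to the margin set."""
    missed = truth_values & ~margin_values
    if not missed.any():
        return 0.0
    m = np.argwhere(missed) * np.asarray(spacing)
    tgt = np.argwhere(margin_values) * np.asarray(spacing)
    return float(cdist(m, tgt).min(axis=1).max())


def brute_point_segment_distance(p, a, b) -> float:
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = np.clip((p - a) @ ab / denom, 0, 1)
    return float(np.linalg.norm(p - (a + t * ab)))


def oracle_decompose(values: np.ndarray, spacing, merge_mm=2.0,
                     connectivity=26):
    """Independent index/satellite decomposition: BFS components, largest
    component (ties: smallest first C-order linear index) as index, then
    iterative merging of components whose pairwise surface distance to the
    current index is below ``merge_mm``."""
    labels = flood_fill_components(values, connectivity)
    n = labels.max()
    if n == 0:
        raise ValueError("empty mask")
    comps = [labels == lab for lab in range(1, n + 1)]
    sizes = [c.sum() for c in comps]
    firsts = [np.flatnonzero(c.ravel())[0] for c in comps]
    order = sorted(range(n), key=lambda i: (-sizes[i], firsts[i]))
    index = comps[order[0]].copy()
    rest = [comps[i] for i in order[1:]]
    changed = True
    while changed and rest:
        changed = False
        keep = []
        for comp in rest:
            if brute_surface_distance(index, comp, spacing) < merge_mm:
                index |= comp
                changed = True
            else:
                keep.append(comp)
        rest = keep
    return index, rest


def random_mask(rng, shape, p=0.15) -> np.ndarray:
    values = rng.random(shape) < p
    if not values.any():
        values[tuple(rng.integers(0, s) for s in shape)] = True
    return values
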