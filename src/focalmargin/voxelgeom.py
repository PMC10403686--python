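"""Voxel-grid conventions and 3D geometry primitives.

All volumes of a case live on one shared :class:`VoxelGrid`. Axis semantics
follow radiological convention for a supine patient: x increases to
patient-left, y to anterior, z from apex to base. Indices are 0-based and
masks use voxel-center semantics: a voxel belongs to a region iff its
center does.

Distances are Euclidean in millimetres and respect anisotropic spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and spacing shared by all volumes of one case.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z). Each component >= 1.
    spacing_mm
        Voxel edge lengths in mm along (x, y, z). Each component > 0.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("grid is three-dimensional")
        if any(s < 1 for s in shape):
            raise ValueError(f"shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) as a sparse open meshgrid."""
        axes = [np.arange(n) * d for n, d in zip(self.shape, self.spacing_mm)]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing_mm)


@dataclass
class Mask:
    """A binary voxel set on a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {values.shape} does not match grid {self.grid.shape}"
            )
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            values = values.astype(bool)
        self.values = values

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3

    def issubset(self, other: "Mask") -> bool:
        _check_same_grid(self, other)
        return bool(np.all(other.values[self.values]))

    def __and__(self, other: "Mask") -> "Mask":
        _check_same_grid(self, other)
        return Mask(self.grid, self.values & other.values)

    def __or__(self, other: "Mask") -> "Mask":
        _check_same_grid(self, other)
        return Mask(self.grid, self.values | other.values)

    def __invert__(self) -> "Mask":
        return Mask(self.grid, ~self.values)


@dataclass
class LabeledRegions:
    """Connected regions of a mask, labeled 1..n by decreasing voxel count.

    ``labels`` is 0 on background. ``table`` maps each positive label to
    ``(voxel_count, volume_mm3)``.
    """

    grid: VoxelGrid
    labels: np.ndarray
    table: dict[int, tuple[int, float]] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def region_mask(self, label: int) -> Mask:
        if label not in self.table:
            raise KeyError(f"no region with label {label}")
        return Mask(self.grid, self.labels == label)


def _check_same_grid(a: Mask, b: Mask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks live on different grids; resampling is not supported")


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def distance_map(mask: Mask) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest mask voxel center.

    Zero on mask voxels; anisotropic spacing respected.

    Raises
    ------
    ValueError
        If the mask is empty ("empty reference set").
    """
    if mask.is_empty:
        raise ValueError("empty reference set")
    return ndimage.distance_transform_edt(
        ~mask.values, sampling=mask.grid.spacing_mm
    )


def components(mask: Mask, connectivity: int = 26) -> LabeledRegions:
    """Maximal connected regions of a mask.

    Labels are assigned deterministically: 1..n by decreasing voxel count,
    ties broken by the smallest linear (C-order) index of a region's first
    voxel. An empty mask yields zero regions.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        return LabeledRegions(mask.grid, np.zeros(mask.grid.shape, dtype=np.int32), {})

    counts = np.bincount(raw.ravel())[1:]  # per raw label 1..n
    # first (smallest) linear index of each raw label, for deterministic ties
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda lab: (-counts[lab - 1], first_idx[lab]))

    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    labels = remap[raw]
    vv = mask.grid.voxel_volume_mm3
    table = {
        new: (int(counts[old - 1]), counts[old - 1] * vv)
        for new, old in enumerate(order, start=1)
    }
    return LabeledRegions(mask.grid, labels, table)


def volume_fraction(mask: Mask, reference: Mask) -> float:
    """Fraction of the reference volume covered by ``mask`` (measured inside it).

    Used for margin volume as a percent of the prostate: the numerator is
    ``mask & reference`` so voxels outside the reference never count.
    """
    _check_same_grid(mask, reference)
    ref_count = reference.count
    if ref_count == 0:
        raise ValueError("empty reference mask")
    return float((mask.values & reference.values).sum()) / ref_count
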