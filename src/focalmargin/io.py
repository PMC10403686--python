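"""NIfTI-1 volume I/O.

Grid spacing is taken from the affine diagonal; volumes with rotated or
sheared affines are rejected rather than resampled, because all volumes of
one case must share a single axis-aligned grid.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .voxelgeom import Mask, VoxelGrid


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0.0, atol=1e-6):
        raise ValueError(
            "non-axis-aligned affine: volumes must be on an axis-aligned grid "
            "(no rotation or shear); resample upstream"
        )
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError("affine diagonal must be nonzero")
    return VoxelGrid(tuple(int(s) for s in shape[:3]), tuple(float(s) for s in spacing))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3D NIfTI volume; returns (data, grid)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    return data, grid


def read_mask(path) -> Mask:
    data, grid = read_volume(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask volume contains non-binary values: {uniq[:10]}")
    return Mask(grid, data.astype(bool))


def write_volume(path, data: np.ndarray, grid: VoxelGrid) -> None:
    if data.shape != grid.shape:
        raise ValueError("data shape does not match grid")
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_mask(path, mask: Mask) -> None:
    write_volume(path, mask.values.astype(np.uint8), mask.grid)


def save_case(case, out_dir) -> None:
    """Write one case as NIfTI volumes plus a JSON record (cores, PSA, slab,
    lesion grades) and a cores CSV."""
    import csv
    import json
    from pathlib import Path
    from .phantom import cores_to_records

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask(out_dir / "gland.nii.gz", case.gland)
    write_mask(out_dir / "truth_cs.nii.gz", case.truth_cs)
    if case.cem is not None:
        write_volume(out_dir / "cem.nii.gz", case.cem, case.grid)
    if case.lesion_labels is not None:
        write_volume(out_dir / "lesion_labels.nii.gz",
                     case.lesion_labels.astype(np.uint8), case.grid)
    for roi in case.roi_list:
        write_mask(out_dir / f"{roi.roi_id}.nii.gz", roi.mask)
    record = {
        "case_id": case.case_id,
        "psa_ng_ml": case.psa_ng_ml,
        "slab": list(case.slab),
        "prior_treatment": case.prior_treatment,
        "lesion_grades": {str(k): v for k, v in case.lesion_grades.items()},
        "rois": [{"roi_id": r.roi_id, "pirads": r.pirads}
                 for r in case.roi_list],
        "cores": [
            {"core_id": c.core_id, "entry_mm": list(c.entry_mm),
             "tip_mm": list(c.tip_mm), "isup_grade": c.isup_grade,
             "cancer_length_mm": c.cancer_length_mm, "targeted": c.targeted,
             "roi_id": c.roi_id,
             "cs_centroid_mm": list(c.cs_centroid_mm)
             if c.cs_centroid_mm else None}
            for c in case.cores
        ],
    }
    (out_dir / "case.json").write_text(json.dumps(record, indent=2))
    rows = cores_to_records(case)
    with open(out_dir / "cores.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def load_case(in_dir):
    """Read a case written by :func:`save_case`."""
    import json
    from pathlib import Path
    from .phantom import BiopsyCore, PatientCase, RoiMask

    in_dir = Path(in_dir)
    record = json.loads((in_dir / "case.json").read_text())
    gland = read_mask(in_dir / "gland.nii.gz")
    truth = read_mask(in_dir / "truth_cs.nii.gz")
    cem = None
    if (in_dir / "cem.nii.gz").exists():
        cem, _ = read_volume(in_dir / "cem.nii.gz")
    labels = None
    if (in_dir / "lesion_labels.nii.gz").exists():
        raw, _ = read_volume(in_dir / "lesion_labels.nii.gz")
        labels = raw.astype(np.int8)
    rois = [RoiMask(r["roi_id"], read_mask(in_dir / f"{r['roi_id']}.nii.gz"),
                    r["pirads"]) for r in record["rois"]]
    cores = [BiopsyCore(c["core_id"], tuple(c["entry_mm"]), tuple(c["tip_mm"]),
                        c["isup_grade"], c["cancer_length_mm"], c["targeted"],
                        c["roi_id"],
                        tuple(c["cs_centroid_mm"])
                        if c["cs_centroid_mm"] else None)
             for c in record["cores"]]
    return PatientCase(
        case_id=record["case_id"], grid=gland.grid, gland=gland,
        truth_cs=truth, roi_list=rois, cores=cores,
        psa_ng_ml=record["psa_ng_ml"], slab=tuple(record["slab"]),
        cem=cem, lesion_labels=labels,
        lesion_grades={int(k): v for k, v in record["lesion_grades"].items()},
        prior_treatment=record["prior_treatment"],
    )
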