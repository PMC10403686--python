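import numpy as np
import pytest

import focalmargin as fm
from focalmargin.phantom import PatientCase
from focalmargin.voxelgeom import Mask, VoxelGrid


@pytest.fixture(scope="session")
def default_config():
    return fm.PhantomConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """12 default phantom cases, shared across the suite."""
    cases, manifest = fm.generate_cohort(default_config, 12, seed=42)
    return cases, manifest


@pytest.fixture(scope="session")
def small_lookup(small_cohort):
    cases, _ = small_cohort
    return fm.calibrate_ecs(cases)


def make_toy_case(cem=None, gland=None, truth=None, shape=(16, 16, 16),
                  spacing=(1.0, 1.0, 1.0), slab=None, cores=(), rois=(),
                  psa=6.9, case_id="toy"):
    """Small hand-constructed case: box gland, box lesion by default."""
    grid = VoxelGrid(shape, spacing)
    if gland is None:
        gland = np.zeros(shape, dtype=bool)
        gland[2:-2, 2:-2, 2:-2] = True
    if truth is None:
        truth = np.zeros(shape, dtype=bool)
        truth[5:9, 5:9, 5:9] = True
        truth &= gland
    if slab is None:
        zs = np.flatnonzero(gland.any(axis=(0, 1)))
        slab = (int(zs[0]), int(zs[-1]))
    labels = np.zeros(shape, dtype=np.int8)
    labels[truth] = 1
    case = PatientCase(
        case_id=case_id, grid=grid, gland=Mask(grid, gland),
        truth_cs=Mask(grid, truth), roi_list=list(rois), cores=list(cores),
        psa_ng_ml=psa, slab=slab, cem=None, lesion_labels=labels,
        lesion_grades={1: 2} if truth.any() else {},
    )
    if cem is not None:
        case.attach_cem(np.asarray(cem, dtype=np.float32))
    return case


@pytest.fixture
def toy_case():
    """Toy case with a CEM that decays with distance from the lesion."""
    case = make_toy_case()
    from scipy import ndimage
    d = ndimage.distance_transform_edt(~case.truth_cs.values)
    cem = np.clip(0.9 - 0.08 * d, 0.0, 1.0).astype(np.float32)
    cem[~case.gland.values] = 0.0
    case.attach_cem(cem)
    return case
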