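import numpy as np
import pytest
from hypothesis import settings

import dpratio as d

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def straight_spec_1mm() -> d.PhantomSpec:
    """Straight concentric tube, R=10 mm, r=2 mm, 60 mm, 1 mm voxels."""
    return d.PhantomSpec(length=60.0, voxel_spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def straight_case_1mm(straight_spec_1mm) -> d.PhantomCase:
    return d.generate_phantom(straight_spec_1mm)


@pytest.fixture(scope="session")
def straight_result_1mm(straight_case_1mm) -> d.CaseResult:
    return d.compute_case_from_masks(straight_case_1mm.pancreas,
                                     straight_case_1mm.duct,
                                     case_id="straight_1mm")


def make_cylinder_mask(n_axial: int = 30, radius_vox: float = 3.5,
                       half_side: int = 5,
                       spacing=(1.0, 1.0, 1.0)) -> d.VoxelMask:
    """Flat-capped solid cylinder along the x (patient-left) axis."""
    side = 2 * half_side + 1
    values = np.zeros((n_axial, side, side), dtype=np.uint8)
    jj, kk = np.meshgrid(np.arange(side) - half_side,
                         np.arange(side) - half_side, indexing="ij")
    disk = (jj ** 2 + kk ** 2) <= radius_vox ** 2
    values[:, disk] = 1
    geometry = d.VolumeGeometry(spacing=np.asarray(spacing, dtype=float),
                                origin=np.zeros(3), direction=np.eye(3))
    return d.VoxelMask(values=values, geometry=geometry, label_name="pancreas")
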