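"""Shared phantom fixtures.

The expensive artefacts (rendered volumes, structure tensors) are built once
per session; tests treat them as read-only.
"""

import numpy as np
import pytest

from myoarch.geometry import GRID45, assign_segments
from myoarch.orientation import structure_tensor
from myoarch.phantom import PhantomSpec, make_vector_phantom, render_intensity

# annulus whose cylindrical frames are exact: wall 200 μm = 20 voxels
ANNULUS_SPEC = PhantomSpec(
    inner_radius_um=300.0,
    outer_radius_um=500.0,
    lv_length_um=800.0,
    voxel_um=10.0,
    stripe_period_um=30.0,
    ha_endo_deg=90.0,
    ha_epi_deg=-50.0,
    ia_base_deg=0.0,
    ia_apex_deg=0.0,
    geometry="annulus",
    seed=11,
)


@pytest.fixture(scope="session")
def annulus_gt():
    return make_vector_phantom(ANNULUS_SPEC)


@pytest.fixture(scope="session")
def annulus_volume(annulus_gt):
    return render_intensity(annulus_gt)


@pytest.fixture(scope="session")
def annulus_orientation(annulus_volume, annulus_gt):
    # 5³ window: the tensor needs more than one texture correlation length
    return structure_tensor(
        annulus_volume, annulus_gt.mask, window_voxels=5,
        gradient_sigma_um=0.7 * ANNULUS_SPEC.voxel_um,
    )


@pytest.fixture(scope="session")
def annulus_segments(annulus_gt):
    return assign_segments(annulus_gt.mask, annulus_gt.axis, GRID45, frames=annulus_gt.frames)


@pytest.fixture(scope="session")
def prolate_gt():
    # realistic half prolate spheroid, rescaled into a ~72³ grid
    return make_vector_phantom(PhantomSpec(seed=7).scaled_to_grid(72))
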