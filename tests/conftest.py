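import numpy as np
import pytest

from musclemetrics import CohortSpec, PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Straight tube r=10 mm, L=60 mm on a (1,1,3) mm grid."""
    spec = PhantomSpec(
        shape_kind="straight_tube",
        axis_length_mm=60.0,
        radius_mm=10.0,
        voxel_spacing_mm=(1.0, 1.0, 3.0),
        rng_seed=1,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def torus_phantom():
    """Quarter-turn curved tube, centreline radius 40 mm, tube radius 4 mm."""
    spec = PhantomSpec(
        shape_kind="curved_tube",
        axis_length_mm=np.pi / 2 * 40.0,
        radius_mm=4.0,
        curvature_per_mm=1.0 / 40.0,
        voxel_spacing_mm=(1.1, 1.1, 1.0),
        rng_seed=0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Default 11-subject bilateral cohort of the 23 analysed muscles."""
    return make_cohort(CohortSpec(n_subjects=11, rng_seed=42))
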