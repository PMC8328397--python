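import dataclasses

import numpy as np
import pytest

from dtialps.cohort import default_cohort_spec, sample_cohort
from dtialps.io import VolumeGeometry
from dtialps.phantom import PhantomSpec, default_phantom_spec


@pytest.fixture(scope="session")
def calibrated_spec():
    """Default cohort spec with calibration done once per session."""
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort_142(calibrated_spec):
    return sample_cohort(calibrated_spec, seed=11)


@pytest.fixture(scope="session")
def phantom_spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact phantom used for replicated noise experiments."""
    return PhantomSpec(
        geometry=VolumeGeometry(shape=(24, 24, 12), voxel_size_mm=(2.0, 2.0, 2.0)),
        ventricle_x=(10, 14),
        proj_x_left=(6, 10),
        proj_x_right=(14, 18),
        assoc_x_left=(2, 6),
        assoc_x_right=(18, 22),
        band_y=(2, 22),
        band_z=(2, 10),
        roi_centers={
            "left_assoc": (4, 12, 6),
            "left_proj": (8, 12, 6),
            "right_proj": (16, 12, 6),
            "right_assoc": (20, 12, 6),
        },
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_spec_factory(calibrated_spec):
    def make(**overrides):
        return dataclasses.replace(calibrated_spec, **overrides)

    return make
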