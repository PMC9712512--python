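import numpy as np
import pytest

from fatfront.profiles import MuscleProfile


def make_profile(ff, n_voxels=None, muscle="m", side="L", timepoint="baseline",
                 positions=None):
    """Profile from raw per-slice values; equal voxel counts by default."""
    ff = np.asarray(ff, dtype=float)
    n = len(ff)
    if n_voxels is None:
        n_voxels = np.full(n, 50)
    if positions is None:
        positions = 100.0 * np.arange(n) / (n - 1)
    return MuscleProfile(
        muscle=muscle, side=side, timepoint=timepoint,
        slice_indices=np.arange(n), ff=ff,
        n_voxels=np.asarray(n_voxels), relative_pos=np.asarray(positions),
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced phantom cohort shared by the slower integration tests."""
    from fatfront.synthetic import SyntheticCohortConfig, SyntheticLegConfig, generate_cohort

    return generate_cohort(SyntheticCohortConfig(
        n_patients=4, n_followup=3,
        leg=SyntheticLegConfig(n_muscles=4, n_slices=60, seed=0),
        seed=0,
    ))
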