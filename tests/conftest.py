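import numpy as np
import pytest
from hypothesis import settings

from fcdseg import LesionMask, Volume
from fcdseg.phantom import PhantomSpec, generate_cohort, generate_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("deterministic")


def make_volume(data, spacing=(1.0, 1.0, 1.0), axial_axis=2) -> Volume:
    return Volume(np.asarray(data), np.diag((*spacing, 1.0)), axial_axis=axial_axis)


def make_mask(data, spacing=(1.0, 1.0, 1.0), axial_axis=2) -> LesionMask:
    return LesionMask(np.asarray(data), np.diag((*spacing, 1.0)), axial_axis=axial_axis)


@pytest.fixture
def phantom_with_info():
    """One default phantom plus the generator's ground truth."""
    return generate_phantom(PhantomSpec(seed=7), with_info=True)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 10-case heterogeneous phantom cohort on disk, shared across tests."""
    root = tmp_path_factory.mktemp("cohort")
    collection = generate_cohort(10, root, seed=11)
    return collection
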