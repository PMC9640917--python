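import numpy as np
import pytest

from mcatnet.cohort import CohortSpec, generate_cohort
from mcatnet.preprocessing import CT_CHANNELS, ModalityStack, RoiPatch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_ct_cohort():
    """Small CT-only cohort with a strong planted arterial-phase signal."""
    spec = CohortSpec(
        n_ct_only=40, n_mri_only=0, n_mixed=0,
        pos_ct_only=20, pos_mri_only=0, pos_mixed=0,
        side=32, ct_effects=(0.0, 3.0, 0.0), mri_effects=(0.0,) * 6, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort_small():
    """Full 121-lesion composition at reduced patch size for speed."""
    return generate_cohort(CohortSpec(side=32))


def make_ct_stack(side=16, fill=0.5, impulse=None):
    """A constant CT stack, optionally with one bright pixel per channel."""
    patches = []
    for name in CT_CHANNELS:
        img = np.full((side, side), fill, dtype=np.float32)
        if impulse is not None:
            img[impulse] = 1.0
        patches.append(RoiPatch(pixels=img, channel_name=name))
    return ModalityStack(channels=patches, modality="CT")
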