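import numpy as np
import pytest

import flairmismatch as fm


@pytest.fixture(scope="session")
def default_case():
    """Noise-free default phantom: fully FLAIR-visible lateral lesion."""
    return fm.generate_phantom()


@pytest.fixture(scope="session")
def default_output(default_case):
    """Full pipeline output on the default phantom (one registration)."""
    return fm.run_case(
        default_case.flair, default_case.dwi_roi, default_case.parenchyma
    )


@pytest.fixture(scope="session")
def symmetric_flair():
    """A perfectly left-right symmetric FLAIR volume (no lesion painted)."""
    case = fm.generate_phantom(fm.PhantomSpec(lesion_fraction_hyper=0.0))
    return case.flair


def random_volume(rng, shape=(12, 10, 8)):
    return fm.ImageVolume(rng.uniform(10, 200, shape), np.eye(4))
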