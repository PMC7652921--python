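import numpy as np
import pytest

from ichseg import (
    PhantomSpec,
    StandardSpec,
    generate_cohort,
    generate_phantom,
    standardize,
)


@pytest.fixture(scope="session")
def std_phantom():
    """One phantom standardized to a 32x32x16 grid: (CTVolume, LabelVolume)."""
    vol, mask = generate_phantom(PhantomSpec(grid=(48, 48, 24), seed=11))
    return standardize(vol, mask, StandardSpec(grid=(32, 32, 16)))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-case phantom cohort on disk with manifest; native grid 32x32x16."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(
        6,
        out,
        spec=PhantomSpec(grid=(32, 32, 16), spacing=(3.0, 3.0, 4.0)),
        split=(4, 1, 1),
        seed=5,
    )
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
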