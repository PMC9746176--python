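import numpy as np
import pytest

import cbctdose as cd
from cbctdose.phantom import CBCTArtifactModel, DeformationSpec, PhantomParams

# tissue table with plateaus separated by >= 200 HU, used by the
# method-recovery tests so class membership is unambiguous by construction
# (all soft tissues stay above the -300 HU air-pocket threshold)
SEPARATED_HU = {
    "air": -1000.0,
    "lung": -750.0,
    "adipose": -250.0,
    "breast_glandular": -40.0,
    "soft_tissue": 170.0,
    "bone": 700.0,
}

SMALL_SHAPE = (72, 72, 40)
SMALL_SPACING = (4.4, 4.4, 4.0)


def small_params(**kw) -> PhantomParams:
    return PhantomParams(shape=SMALL_SHAPE, spacing=SMALL_SPACING, **kw)


@pytest.fixture(scope="session")
def standard_case() -> cd.PhantomCase:
    """One fully corrupted study case on the scaled-down cohort grid."""
    return cd.generate_case(small_params(), DeformationSpec(peak_mm=8.0),
                            CBCTArtifactModel(), seed=1)


@pytest.fixture(scope="session")
def separated_case() -> cd.PhantomCase:
    """Corrupted case whose tissue plateaus are >= 200 HU apart."""
    return cd.generate_case(
        small_params(tissue_hu=dict(SEPARATED_HU)),
        DeformationSpec(peak_mm=8.0),
        CBCTArtifactModel(),
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless piecewise-constant phantom and structures (no artifacts)."""
    params = small_params(noise_sigma=0.0)
    return cd.generate_phantom(params) + (params,)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
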