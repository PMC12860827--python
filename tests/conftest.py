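import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from petmiv.phantom import CohortSpec, Lesion, PhantomSpec, generate_cohort, generate_phantom

# A lesion center well inside the right lung field of the default 64^3 /
# 2 mm grid (lung center x=37.8, y=63, z=60.5; apex cap above z~110).
RIGHT_LUNG_CENTER = (37.8, 63.0, 55.0)
LEFT_LUNG_CENTER = (88.2, 63.0, 55.0)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Clean phantom with one detectable sphere: r=10 mm, multiplier 3."""
    spec = PhantomSpec(lesions=(Lesion(RIGHT_LUNG_CENTER, 10.0, 3.0),))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
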