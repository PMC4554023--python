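import numpy as np
import pytest

from astigvec import CylAstig, EyeRecord, SpheroCylinder, SimulationParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_eye():
    """A hand-built eye with all fields populated."""
    return EyeRecord(
        eye_id="eye1",
        age=70.0,
        ak=CylAstig(1.0, 0.0),
        tcrp3=CylAstig(1.2, 10.0),
        tcrp4=CylAstig(1.1, 5.0),
        ir=0.04,
        irregular_astig=0.4,
        anterior_radius=7.8,
        posterior_radius=6.5,
        ra_postop=SpheroCylinder(sphere=-0.5, cylinder=-0.75, axis=95.0, notation="negative"),
        spherical_aberration=0.35,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimulationParams(n=200, seed=11))


def random_cyl(rng, n):
    """n random CylAstig values with magnitude in [0, 6) and any axis."""
    mags = rng.uniform(0.0, 6.0, n)
    axes = rng.uniform(0.0, 180.0, n)
    return [CylAstig(float(m), float(a) % 180.0) for m, a in zip(mags, axes)]
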