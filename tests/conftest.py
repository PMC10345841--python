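import numpy as np
import pytest

from bodycomp.phantom import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact phantom, fast enough to regenerate in several tests."""
    return PhantomSpec(
        body_semiaxes=(110.0, 80.0),
        sat_thickness=20.0,
        muscle_thickness=12.0,
        grid_size=(128, 128),
        pixel_spacing=(2.0, 2.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noise_free_cohort():
    spec = CohortSpec(noise_sd=0.0, seed=5)
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
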