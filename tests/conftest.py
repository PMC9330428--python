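import dataclasses

import numpy as np
import pytest

from renalseg.config import resolve_config
from renalseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def desk_cfg():
    return resolve_config("desk", seed=0)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast phantom with one medium and one small-ish stone."""
    return PhantomSpec(
        shape_zyx=(24, 64, 64),
        spacing_mm=(2.0, 1.0, 1.0),
        kidney_axes_mm=((14.0, 16.0), (9.0, 11.0), (9.0, 11.0)),
        stone_diameters_mm=(7.0, 4.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec, case_id="tiny")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def noiseless(spec: PhantomSpec) -> PhantomSpec:
    return dataclasses.replace(spec, noise_sd_hu=0.0)
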