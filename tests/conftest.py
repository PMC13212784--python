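"""Shared fixtures: small, fast head phantoms for unit tests.

The small phantom keeps the full anatomy (skull shell, CSF margin, textured
parenchyma, paired ventricles, one lesion) on a 64x80x56 grid so registration
and pooling stay fast; pipeline-level acceptance checks use the default-size
phantom instead.
"""
from dataclasses import replace

import numpy as np
import pytest

from nwuct.config import RunConfig
from nwuct.phantom import PhantomSpec, generate_phantom

SMALL_SHAPE = (64, 80, 56)
SMALL_SKULL = (28.0, 36.0, 24.0)


def small_spec(**overrides) -> PhantomSpec:
    base = PhantomSpec(
        shape=SMALL_SHAPE,
        skull_outer=SMALL_SKULL,
        skull_thickness=3.0,
        csf_margin=2.0,
        ventricle_center=(6.0, -4.0, 2.0),
        ventricle_radii=(3.0, 9.0, 5.0),
        texture_amplitude=0.05,
        texture_scale_mm=8.0,
        seed=0,
    )
    return replace(base, **overrides)


@pytest.fixture(scope="session")
def small_template():
    spec = small_spec(texture_amplitude=0.0)
    return generate_phantom(spec).ct


@pytest.fixture(scope="session")
def lesion_case():
    """Small phantom with a 4 mL left-hemisphere lesion at 15% uptake."""
    spec = small_spec(uptake_percent=15.0, noise_sigma=1.0,
                      lesion_center=(-11.0, 1.0, 0.0),
                      lesion_radii=(8.0, 12.0, 10.0), seed=42)
    return generate_phantom(spec)


#: pipeline configuration matched to the miniature grid: the pooling window
#: is scaled down with the anatomy so a ~4 mL lesion is still resolvable
SMALL_CFG = dict(kernel_mm=(7.0, 7.0, 7.0))


@pytest.fixture(scope="session")
def pipeline_output(lesion_case, small_template):
    from nwuct.pipeline import run_case

    return run_case(lesion_case.ct, small_template, RunConfig(seed=5, **SMALL_CFG))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
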