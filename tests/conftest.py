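import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modiolus.anatomy import mean_anatomy
from modiolus.spiral import circle_template, scale_template

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_circle_pair(mod_radius: float, lat_radius: float, theta_max: float = 720.0,
                     step_deg: float = 22.5):
    """Concentric flat-circle phantom: (modiolar, lateral) wall spirals."""
    mod_t = circle_template(mod_radius, "modiolar", theta_max, step_deg)
    lat_t = circle_template(lat_radius, "lateral", theta_max, step_deg)
    modiolar = scale_template(mod_t, 2 * mod_radius, 2 * mod_radius)
    lateral = scale_template(lat_t, 2 * lat_radius, 2 * lat_radius)
    return modiolar, lateral


@pytest.fixture(scope="session")
def circle_phantom():
    """The worked concentric phantom: modiolar r=2 mm, lateral R=4.5 mm."""
    return make_circle_pair(2.0, 4.5)


@pytest.fixture(scope="session")
def mean_walls():
    """Packaged templates scaled to the corrosion-cast mean measures."""
    return mean_anatomy()
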