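import numpy as np
import pytest

from hpsforge import baseline_config, generate_ideal_biv
from hpsforge.fascicle import build_fascicle_hps, select_se_layer
from hpsforge.geometry import GeometryParams
from hpsforge.purkinje import build_full_purkinje


@pytest.fixture(scope="session")
def baseline():
    return baseline_config()


@pytest.fixture(scope="session")
def geo():
    """Default synthetic biventricular mesh + UVC frame (built once)."""
    return generate_ideal_biv()


@pytest.fixture(scope="session")
def mesh(geo):
    return geo[0]


@pytest.fixture(scope="session")
def frame(geo):
    return geo[1]


@pytest.fixture(scope="session")
def layer(geo, baseline):
    eas = baseline[0]
    return select_se_layer(geo[1], eas, geo[0])


@pytest.fixture(scope="session")
def fascicle_hps(geo, layer, baseline):
    eas, fas, _, _ = baseline
    return build_fascicle_hps(geo[1], layer, eas, fas)


@pytest.fixture(scope="session")
def full_net(geo, layer, baseline):
    """Baseline Purkinje HPS with PVJs and transmural extension, seed 1."""
    eas, _, purk, _ = baseline
    return build_full_purkinje(geo[0], geo[1], layer, eas, purk, seed=1)


@pytest.fixture(scope="session")
def sphere_params():
    """Spherical-shell variant: equal semi-axes give a uniform LV wall thickness."""
    return GeometryParams(
        lv_long_axis=30.0,
        lv_endo_radius=30.0,
        lv_wall_thickness=8.0,
        rv_offset=30.0,
        rv_long_axis=26.0,
        rv_endo_radius=24.0,
        rv_wall_thickness=4.0,
        base_fraction=0.3,
        target_edge_length=4.0,
    )


@pytest.fixture(scope="session")
def sphere_geo(sphere_params):
    return generate_ideal_biv(sphere_params)


def rng(seed=0):
    return np.random.default_rng(seed)
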