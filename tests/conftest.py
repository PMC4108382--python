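import numpy as np
import pytest

from protomap.architecture import (
    LayerGeometry,
    NetworkGeometry,
    WiringConfig,
    build_network,
    smoke_geometry,
)
from protomap.stimulus import BarStimulusSpec


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def smoke_geom():
    return smoke_geometry()


def smoke_wiring(**overrides) -> WiringConfig:
    """Wiring with spreads scaled down to the 12x12 smoke cortex."""
    kwargs = dict(
        cf_mode="cf5",
        sigma_exc=1.5,
        sigma_inh=3.0,
        exc_cutoff=2.5,
        inh_inner=2.5,
        inh_outer=8.0,
    )
    kwargs.update(overrides)
    return WiringConfig(**kwargs)


def smoke_bar(direction="E", **overrides) -> BarStimulusSpec:
    kwargs = dict(
        direction=direction,
        sensor_shape=(64, 64),
        bar_length_px=64,
        bar_width_px=8,
        speed_px_per_s=64.0,
    )
    kwargs.update(overrides)
    return BarStimulusSpec(**kwargs)


@pytest.fixture(scope="session")
def smoke_network(smoke_geom):
    return build_network(smoke_wiring(), smoke_geom, seed=42)


@pytest.fixture(scope="session")
def relay_geometry():
    """A tiny geometry for single-tile relay tests: one LGN neuron per 4x4."""
    return NetworkGeometry(
        input=LayerGeometry("input", 8, 8),
        lgn=LayerGeometry("lgn", 2, 2),
        cortex=LayerGeometry("cortex", 2, 2),
    )
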