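import numpy as np
import pytest

from synthflow import cli, phantom


@pytest.fixture(scope="session")
def tiny_field():
    """Steady 16^3 turbulent phantom used across modules."""
    return cli.make_fixtures("tiny")


@pytest.fixture(scope="session")
def small_pulsatile():
    """5-frame pulsatile 24x24x32 phantom with a configured turbulence lag."""
    return cli.make_fixtures("small")


@pytest.fixture(scope="session")
def jet_field():
    """Steady phantom on a finer (0.8 mm) grid, roomy enough for downsampling."""
    grid = phantom.Grid3D(shape=(28, 28, 48), spacing=(0.8, 0.8, 0.8))
    spec = phantom.StenosisSpec(
        diameter=10.0,
        throat_position=0.8,
        downstream_length=2.6,
        stenosis_length=1.0,
    )
    turb = phantom.TurbulenceSpec(tke_peak=120.0, peak_offset=1.0)
    return phantom.make_phantom_flow(spec, phantom.InletSpec(), grid, turb)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def venc_ladder(field, factor=1.3, ratio=2.0, n=3):
    """Three-level geometric VENC ladder spanning a field's velocity range."""
    vmax = factor * float(np.abs(field.u_mean).max())
    return tuple(vmax / ratio**i for i in range(n))
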