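import numpy as np
import pytest

from preyscape import acoustics
from preyscape.synthetic import SimConfig, simulate_scene, simulate_survey


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noise-free study-shaped configuration with the detection floor lowered
    so weak background scattering stays measurable (forward-inverse checks)."""
    return SimConfig(noise_sd_db=0.0, detection_floor_db=-300.0, seed=7)


@pytest.fixture(scope="session")
def scene(quiet_cfg):
    return simulate_scene(quiet_cfg)


@pytest.fixture(scope="session")
def cleaned_survey(scene, quiet_cfg):
    pings = simulate_survey(scene, quiet_cfg)
    return acoustics.clean_echogram(pings)


def make_pingset(sv_rows, depths=None, times=None, x=None, y=None, **kw):
    """Small hand-built PingSet for unit tests."""
    sv = np.atleast_2d(np.asarray(sv_rows, dtype=float))
    n, m = sv.shape
    depths = np.arange(m) + 5.5 if depths is None else np.asarray(depths, float)
    times = np.arange(n, dtype=float) * 0.5 if times is None else times
    x = np.arange(n, dtype=float) if x is None else x
    y = np.zeros(n) if y is None else y
    return acoustics.PingSet(times, x, y, depths, sv, **kw)
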