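import numpy as np
import pytest

from fibroegm.ionic import AF_REMODELED
from fibroegm.propagation import SimulationConfig, calibrate_conductivity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cv_scales():
    """Conductivity scales hitting 30 and 40 cm/s on the strand."""
    cfg = SimulationConfig()
    return {cv: calibrate_conductivity(cv, AF_REMODELED, cfg) for cv in (30.0, 40.0)}


@pytest.fixture(scope="session")
def small_sim():
    """One small control patch simulation shared across tests.

    10 x 10 x 1 mm patch at 0.25 mm, 1.3 s trace with 2 beats, contact
    HD-grid (reduced 1.5 mm spacing) -- fast but fully representative.
    """
    from dataclasses import replace

    from fibroegm.electrodes import hd_grid, simulate_unipolar
    from fibroegm.propagation import StimulusProtocol
    from fibroegm.tissue import build_tissue

    cfg = SimulationConfig()
    scale = calibrate_conductivity(30.0, AF_REMODELED, cfg)
    cfg = replace(cfg, cond_scale=scale, trace_length=1.3)
    grid = build_tissue((10.0, 10.0, 1.0), 0.25)
    lay = hd_grid((5.0, 5.0), spacing=1.5)
    protocol = StimulusProtocol(site="left-edge", n_beats=2)
    uni, field = simulate_unipolar(
        grid, AF_REMODELED, protocol, cfg, lay, record_field=True
    )
    return {
        "grid": grid,
        "layout": lay,
        "config": cfg,
        "protocol": protocol,
        "uni": uni,
        "field": field,
    }
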