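from __future__ import annotations

import numpy as np
import pytest

from icekit import AnalysisParams, Configuration
from icekit.icedetect import SwitchingParams
from icekit.synthio import build_ice_ih, build_liquid_slab, build_polymer


@pytest.fixture(scope="session")
def default_params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture(scope="session")
def growth_params() -> AnalysisParams:
    """First-shell switching range: robust exact counting on scripted growth."""
    return AnalysisParams(switching=SwitchingParams(r_cut=0.42))


@pytest.fixture(scope="session")
def ice_slab() -> Configuration:
    return build_ice_ih(4, 3, 6, seed=0)


@pytest.fixture(scope="session")
def liquid_box() -> Configuration:
    return build_liquid_slab((3.0, 3.0, 3.0), 33.0, 0.26, seed=1)


@pytest.fixture(scope="session")
def pva20():
    return build_polymer("VA*20", seed=0)


def make_gas_config(
    n: int,
    box,
    seed: int,
    pbc_mode: str = "xyz",
    min_dist: float = 0.25,
) -> Configuration:
    """Random water-oxygen gas with dummy hydrogens (helper, not a fixture)."""
    from icekit.synthio.liquid import insert_points, random_water_orientations
    from icekit.synthio.lattice import _water_config

    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    o = insert_points(n, box, min_dist, rng, pbc_mode=pbc_mode)
    h = o[:, None, :] + random_water_orientations(n, rng)
    return _water_config(o, h, box, pbc_mode=pbc_mode)
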