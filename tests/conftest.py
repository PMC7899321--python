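import numpy as np
import pytest

from renestsim import SiteParams, SpeciesParams, WaterYear


@pytest.fixture
def params() -> SpeciesParams:
    return SpeciesParams()


@pytest.fixture
def site() -> SiteParams:
    return SiteParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_water_year(level: float = 425.0, doy_start: int = 91, doy_end: int = 273, year_id: str = "flat") -> WaterYear:
    """A constant-level season, handy for dry / fully-flooded edge cases."""
    n = doy_end - doy_start + 1
    return WaterYear(year_id=year_id, levels=np.full(n, level), doy_start=doy_start)


@pytest.fixture
def dry_year() -> WaterYear:
    """Water always far below any nest site: no flooding, no inundation."""
    return make_water_year(425.0, year_id="dry")
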