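import numpy as np
import pandas as pd
import pytest

from vinecast.canopy import VineyardGeometry
from vinecast.synthetic import WeatherGenParams, gen_weather


@pytest.fixture(scope="session")
def calibration_geometry() -> VineyardGeometry:
    """The 35° NE–SW trained-wall row the light/transpiration models were
    calibrated on: 45.1°N, 2.5 m alleys, ~1.3 m canopy wall, 0.4 m thick."""
    return VineyardGeometry(
        latitude=45.1,
        longitude=9.6,
        altitude=60.0,
        row_azimuth=35.0,
        row_spacing=2.5,
        canopy_height=1.3,
        canopy_width=0.4,
        canopy_base_height=0.9,
    )


@pytest.fixture(scope="session")
def weather_year() -> pd.DataFrame:
    daily, _ = gen_weather(WeatherGenParams(seed=11), 2022, subdaily=False)
    return daily


@pytest.fixture(scope="session")
def weather_with_subdaily() -> tuple[pd.DataFrame, pd.DataFrame]:
    return gen_weather(WeatherGenParams(seed=11), 2022)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
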