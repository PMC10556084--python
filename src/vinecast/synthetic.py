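"""Seeded synthetic weather, vineyards, phenology and transpiration data.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable end to end without field data.  Daily
temperature follows an annual sinusoid with AR(1) noise; radiation is the
site's clear-sky total scaled by a daily clearness index; precipitation is
a Bernoulli-occurrence / gamma-amount chain; phenology truth is a pure
GDD-threshold crossing with integer jitter; transpiration observations are
the intercept-free quadratic evaluated on the simulated drivers plus
Gaussian noise.  Vineyard geometries sample the envelopes of the trained
vineyards the models target (row spacing 2.0–3.4 m, canopy height
0.9–1.4 m, width 0.30–0.50 m, altitude 27–430 m).

All draws derive from ``numpy.random.default_rng`` seeds; the same seed
reproduces every series bit-exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .canopy import VineyardGeometry
from .phenology import cumulative_gdd, daily_vpd, reference_etp, saturation_vapour_pressure
from .transpiration import CALIBRATED_MODELS, TcModel, predict_tc
from .water_balance import FloorManagement, SoilProfile, pedotransfer

__all__ = [
    "WeatherGenParams",
    "TruthParams",
    "gen_weather",
    "gen_phenology",
    "gen_tc_observations",
    "gen_vineyard",
    "gen_site_years",
]


@dataclass(frozen=True)
class WeatherGenParams:
    """Knobs of the stochastic daily/sub-daily weather generator.

    Defaults describe a northern-Italian mid-latitude site: annual mean
    13 °C with a 10.5 °C seasonal amplitude peaking in late July, a 9 °C
    mean diurnal range and ~25 % wet days.
    """

    latitude: float = 45.1
    longitude: float = 9.6
    altitude_m: float = 100.0
    tmean_annual: float = 13.0
    annual_amplitude: float = 10.5
    peak_doy: int = 205
    diurnal_amplitude: float = 9.0
    noise_sd: float = 1.5
    noise_ar1: float = 0.7
    clearness_min: float = 0.25
    clearness_max: float = 0.80
    clearness_beta_a: float = 5.0
    clearness_beta_b: float = 2.0
    precip_prob: float = 0.25
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 6.0
    rh_base: float = 68.0
    rh_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "rh_sd", "precip_gamma_shape", "precip_gamma_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.precip_prob <= 1:
            raise ValueError("precip_prob must be in [0, 1]")


@dataclass(frozen=True)
class TruthParams:
    """Ground truth behind synthetic phenology and transpiration.

    Stage thresholds are cumulative GDD (base 10 °C) from 1 January, in
    the order budburst < flowering < veraison; event dates are the first
    crossing day plus rounded N(0, jitter_sd) days.
    """

    gdd_thresholds: dict = field(
        default_factory=lambda: {"budburst": 15.0, "flowering": 380.0, "veraison": 1100.0}
    )
    jitter_sd_days: float = 2.0
    tc_model: TcModel = field(default_factory=lambda: CALIBRATED_MODELS["2022-06-20"])
    tc_noise_frac: float = 0.05
    soil_sand_pct: float = 20.0
    soil_clay_pct: float = 35.0
    soil_om_pct: float = 1.8
    soil_depth_m: float = 1.0

    def __post_init__(self) -> None:
        t = self.gdd_thresholds
        if not t["budburst"] < t["flowering"] < t["veraison"]:
            raise ValueError("stage thresholds must be ordered budburst < flowering < veraison")


SUBDAILY_STEP_MIN = 30.0


def _clear_sky_daily_mj(params: WeatherGenParams, doy: int) -> float:
    """Clear-sky daily global radiation (MJ m⁻² day⁻¹) by quadrature."""
    hours = np.arange(0.25, 24.0, 0.5)
    watts = 0.0
    for h in hours:
        ang = solar.solar_position(params.latitude, params.longitude, doy, float(h))
        comp = solar.clear_sky_components(ang, doy, params.altitude_m)
        watts += (comp.direct_horizontal + comp.diffuse_horizontal) / solar.PHOTONS_PER_JOULE_SHORTWAVE
    return watts * 1800.0 / 1e6


def gen_weather(
    params: WeatherGenParams, year: int = 2022, subdaily: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """One calendar year of daily weather plus a 30-min sub-daily grid.

    Returns (daily, subdaily).  Daily columns: date, doy, tmin, tmean,
    tmax, rh_pct, wind, radiation (MJ m⁻² day⁻¹), precip_mm, tsoil,
    vpd_kpa, etp_mm, clearness.  Sub-daily columns: date, time (solar
    hours), temp_c, vpd_hpa, direct_light (µmol m⁻² s⁻¹).  The sub-daily
    temperature is a zero-mean diurnal wave around the daily mean, so the
    two resolutions agree by construction.
    """
    rng = np.random.default_rng(params.seed)
    start = dt.date(year, 1, 1)
    n_days = (dt.date(year + 1, 1, 1) - start).days
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    doys = np.arange(1, n_days + 1)

    season = params.tmean_annual + params.annual_amplitude * np.cos(
        2.0 * np.pi * (doys - params.peak_doy) / 365.25
    )
    noise = np.zeros(n_days)
    eps = rng.normal(0.0, params.noise_sd, n_days)
    for i in range(1, n_days):
        noise[i] = params.noise_ar1 * noise[i - 1] + eps[i]
    tmean = season + noise
    tmin = tmean - params.diurnal_amplitude / 2.0
    tmax = tmean + params.diurnal_amplitude / 2.0

    wet = rng.random(n_days) < params.precip_prob
    amounts = rng.gamma(params.precip_gamma_shape, params.precip_gamma_scale, n_days)
    precip = np.where(wet, amounts, 0.0)

    clearness = params.clearness_min + (params.clearness_max - params.clearness_min) * rng.beta(
        params.clearness_beta_a, params.clearness_beta_b, n_days
    )
    clearness = np.where(wet, clearness * 0.5, clearness)

    clear_sky_mj = np.array([_clear_sky_daily_mj(params, int(d)) for d in doys])
    radiation = clear_sky_mj * clearness / 0.75  # 0.75 = generator's clear-sky transmittance

    rh = params.rh_base + rng.normal(0.0, params.rh_sd, n_days) + np.where(wet, 12.0, 0.0)
    rh = np.clip(rh - 0.8 * noise, 25.0, 98.0)

    wind = rng.gamma(2.0, 1.1, n_days)
    tsoil = pd.Series(tmean).rolling(5, min_periods=1).mean().to_numpy()

    daily = pd.DataFrame(
        {
            "date": dates,
            "doy": doys,
            "tmin": tmin,
            "tmean": tmean,
            "tmax": tmax,
            "rh_pct": rh,
            "wind": wind,
            "radiation": radiation,
            "precip_mm": precip,
            "tsoil": tsoil,
            "clearness": clearness,
        }
    )
    daily["vpd_kpa"] = daily_vpd(daily["tmean"], daily["rh_pct"])
    daily["etp_mm"] = reference_etp(
        tmin, tmax, rh, wind, radiation, params.latitude, doys, params.altitude_m
    )
    if not subdaily:
        return daily, None

    hours = np.arange(SUBDAILY_STEP_MIN / 60.0 / 2.0, 24.0, SUBDAILY_STEP_MIN / 60.0)
    sub_rows = []
    for i, (date, doy) in enumerate(zip(dates, doys)):
        wave = -np.cos(2.0 * np.pi * (hours - 2.0) / 24.0)  # trough ~02:00, peak ~14:00
        wave = wave - wave.mean()  # exact zero mean on the uniform grid
        temp = tmean[i] + params.diurnal_amplitude / 2.0 * wave
        vpd_hpa = 10.0 * saturation_vapour_pressure(temp) * (1.0 - rh[i] / 100.0)
        light = np.empty_like(hours)
        for j, h in enumerate(hours):
            ang = solar.solar_position(params.latitude, params.longitude, int(doy), float(h))
            comp = solar.clear_sky_components(ang, int(doy), params.altitude_m)
            light[j] = comp.direct_horizontal * clearness[i] / 0.75
        sub_rows.append(
            pd.DataFrame(
                {
                    "date": date,
                    "time": hours,
                    "temp_c": temp,
                    "vpd_hpa": np.maximum(vpd_hpa, 0.0),
                    "direct_light": light,
                }
            )
        )
    subdaily = pd.concat(sub_rows, ignore_index=True)
    return daily, subdaily


def gen_phenology(
    weather_daily: pd.DataFrame, truth: TruthParams, seed: int = 0
) -> dict[str, int | None]:
    """Stage event DOYs from GDD-threshold crossings plus jitter.

    A stage whose threshold is never reached within the year is None.
    """
    rng = np.random.default_rng(seed)
    gdd = cumulative_gdd(weather_daily["tmean"])
    doys = weather_daily["doy"].to_numpy()
    events: dict[str, int | None] = {}
    for stage, threshold in truth.gdd_thresholds.items():
        crossed = np.nonzero(gdd >= threshold)[0]
        if len(crossed) == 0:
            events[stage] = None
            continue
        jitter = int(round(rng.normal(0.0, truth.jitter_sd_days)))
        doy = int(doys[crossed[0]]) + jitter
        events[stage] = int(np.clip(doy, 1, int(doys[-1])))
    return events


def gen_tc_observations(
    truth: TruthParams,
    tcli_profile: pd.DataFrame,
    weather_subdaily: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy transpiration observations on the sub-daily grid.

    TCLI is interpolated onto the weather grid; y = quadratic(truth) +
    N(0, tc_noise_frac × max signal), clamped at zero.  Columns:
    time, x1, x2, x3, y.
    """
    rng = np.random.default_rng(seed)
    t = weather_subdaily["time"].to_numpy(dtype=float)
    x3 = np.interp(
        t,
        tcli_profile["time"].to_numpy(dtype=float),
        tcli_profile["tcli_percent"].to_numpy(dtype=float),
        left=100.0,
        right=100.0,
    )
    x1 = weather_subdaily["direct_light"].to_numpy(dtype=float)
    x2 = weather_subdaily["vpd_hpa"].to_numpy(dtype=float)
    clean = predict_tc(truth.tc_model, x1, x2, x3)
    scale = truth.tc_noise_frac * float(np.max(clean)) if np.max(clean) > 0 else 0.0
    y = np.maximum(clean + rng.normal(0.0, scale, len(t)) if scale > 0 else clean, 0.0)
    return pd.DataFrame({"time": t, "x1": x1, "x2": x2, "x3": x3, "y": y})


# Envelopes of the calibration vineyards (min, max).
_GEOMETRY_ENVELOPES = {
    "row_spacing": (2.0, 3.4),
    "canopy_height": (0.9, 1.4),
    "canopy_width": (0.30, 0.50),
    "altitude": (27.0, 430.0),
    "latitude": (44.0, 45.0),
    "longitude": (9.0, 11.0),
}

_TEXTURES = {
    "clay_loam": (32.0, 32.0),
    "silty_clay_loam": (10.0, 33.0),
    "clay": (20.0, 45.0),
}


def gen_vineyard(seed: int = 0) -> tuple[VineyardGeometry, SoilProfile, FloorManagement]:
    """Random plausible vineyard: geometry, soil and floor management."""
    rng = np.random.default_rng(seed)
    env = {k: rng.uniform(*v) for k, v in _GEOMETRY_ENVELOPES.items()}
    geometry = VineyardGeometry(
        latitude=env["latitude"],
        longitude=env["longitude"],
        altitude=env["altitude"],
        row_azimuth=float(rng.choice([0.0, 35.0, 90.0, 135.0])),
        row_spacing=env["row_spacing"],
        canopy_height=env["canopy_height"],
        canopy_width=env["canopy_width"],
        canopy_base_height=0.6,
        slope=float(rng.uniform(0.0, 8.0)),
        aspect=float(rng.uniform(0.0, 360.0)),
    )
    sand, clay = _TEXTURES[str(rng.choice(list(_TEXTURES)))]
    soil = pedotransfer(sand, clay, om_pct=float(rng.uniform(1.0, 2.5)), depth_m=1.0)
    termination = dt.date(2022, 5, 18)
    floor = FloorManagement(
        zones=(("winter_cover_crop", 0.7), ("tilled", 0.3)),
        termination_date=termination,
    )
    return geometry, soil, floor


def gen_site_years(
    n: int,
    truth: TruthParams | None = None,
    seed: int = 0,
    year: int = 2022,
) -> list[dict]:
    """Independent synthetic site-years for the phenology harness.

    Each site-year gets its own climate (annual mean drawn from
    U(11.5, 14.5) °C, latitude U(44, 45.5)) and its own weather and
    phenology seeds, all derived from the root seed.  Returns dicts with
    keys site_year, params, weather (daily), events.
    """
    truth = truth or TruthParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    rng = np.random.default_rng(root.spawn(1)[0])
    out = []
    for i, child in enumerate(children):
        w_seed, p_seed = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)]
        params = WeatherGenParams(
            latitude=float(rng.uniform(44.0, 45.5)),
            tmean_annual=float(rng.uniform(11.5, 14.5)),
            annual_amplitude=float(rng.uniform(9.5, 11.5)),
            seed=w_seed,
        )
        daily, _ = gen_weather(params, year, subdaily=False)
        events = gen_phenology(daily, truth, p_seed)
        out.append(
            {
                "site_year": f"SY{i:03d}",
                "params": params,
                "latitude": params.latitude,
                "weather": daily,
                "events": events,
            }
        )
    return out
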