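"""Seasonal soil water balance and stoplight drought warnings.

A single-bucket reservoir holds the plant-available water (SAW) of the
rooted profile — the moisture between field capacity and wilting point,
both estimated from texture and organic matter with the Saxton & Rawls
(2006) pedotransfer functions.  Each day the bucket gains precipitation
and loses floor evapotranspiration (ETs, from a measured anchor schedule)
plus canopy transpiration (Tc); excess above capacity leaves as deep
percolation, demand beyond the stored water is truncated as unmet demand.

Warnings follow the remaining SAW percentage: green above 60 %, yellow in
(40, 60], red at or below 40 % — boundary points go to the more severe
class, the conservative choice for an alert system.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoilProfile",
    "FloorManagement",
    "WaterBalanceDay",
    "pedotransfer",
    "ets_daily",
    "step_balance",
    "classify_warning",
    "run_season",
    "COVER_CLASSES",
]

COVER_CLASSES = (
    "tilled",
    "spontaneous_grass",
    "winter_cover_crop",
    "rolled_mulch",
    "herbicide_strip",
)

#: Deep-winter floor water use common to every cover class, mm/day.
WINTER_BASELINE_MM = 0.3

#: In-season floor water use per cover class, mm/day.  Tilled and winter
#: cover crop are measured anchors; spontaneous grass and herbicide strip
#: are set relative to them (grassed ≈ cover crop, sprayed strip ≈ slightly
#: below bare tilled soil).
SEASON_RATE_MM = {
    "tilled": 1.6,
    "spontaneous_grass": 2.5,
    "winter_cover_crop": 2.7,
    "herbicide_strip": 1.4,
}

#: Post-rolling decay of the terminated cover crop: (days after
#: termination, mm/day) anchors, linear in between, flat after the last.
ROLLED_ANCHORS = ((0, 2.7), (1, 2.0), (14, 0.5), (30, WINTER_BASELINE_MM))

# Growing-season envelope (DOY): linear shoulders between the winter
# baseline and the in-season plateau.
_SEASON_START, _SEASON_FULL = 91, 120
_SEASON_FADE, _SEASON_END = 280, 304


@dataclass(frozen=True)
class SoilProfile:
    """Texture-derived water retention over the rooted depth."""

    sand_pct: float
    clay_pct: float
    om_pct: float
    depth_m: float
    theta_fc: float
    theta_wp: float
    saw_capacity_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_wp < self.theta_fc < 1:
            raise ValueError(
                f"require 0 < wilting point < field capacity < 1, got "
                f"wp={self.theta_wp:.3f}, fc={self.theta_fc:.3f}"
            )


def pedotransfer(
    sand_pct: float, clay_pct: float, om_pct: float, depth_m: float = 1.0
) -> SoilProfile:
    """Saxton & Rawls (2006) retention at 33 and 1500 kPa from texture + OM.

    ``sand_pct``/``clay_pct`` are mass percentages of the mineral fraction,
    ``om_pct`` the organic-matter mass percentage.  Default rooted depth is
    1 m.
    """
    if sand_pct < 0 or clay_pct < 0 or sand_pct + clay_pct > 100:
        raise ValueError(
            f"impossible texture: sand={sand_pct}%, clay={clay_pct}%"
        )
    if om_pct < 0:
        raise ValueError("organic matter must be >= 0")
    if depth_m <= 0:
        raise ValueError("depth must be > 0")
    s, c, om = sand_pct / 100.0, clay_pct / 100.0, om_pct
    t1500 = (
        -0.024 * s + 0.487 * c + 0.006 * om
        + 0.005 * s * om - 0.013 * c * om + 0.068 * s * c + 0.031
    )
    theta_wp = t1500 + (0.14 * t1500 - 0.02)
    t33 = (
        -0.251 * s + 0.195 * c + 0.011 * om
        + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299
    )
    theta_fc = t33 + (1.283 * t33**2 - 0.374 * t33 - 0.015)
    return SoilProfile(
        sand_pct=sand_pct,
        clay_pct=clay_pct,
        om_pct=om_pct,
        depth_m=depth_m,
        theta_fc=theta_fc,
        theta_wp=theta_wp,
        saw_capacity_mm=(theta_fc - theta_wp) * depth_m * 1000.0,
    )


@dataclass(frozen=True)
class FloorManagement:
    """Area-weighted mix of floor cover zones.

    ``zones`` is a sequence of (cover_class, area_fraction) summing to 1.
    ``termination_date`` marks the spring rolling of a winter cover crop;
    after it, winter_cover_crop zones follow the rolled-mulch decay.
    """

    zones: tuple[tuple[str, float], ...]
    termination_date: dt.date | None = None

    def __post_init__(self) -> None:
        zones = tuple((str(c), float(f)) for c, f in self.zones)
        object.__setattr__(self, "zones", zones)
        for cover, frac in zones:
            if cover not in COVER_CLASSES:
                raise ValueError(f"unknown cover class {cover!r}")
            if frac < 0:
                raise ValueError("area fractions must be >= 0")
        total = sum(f for _, f in zones)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"area fractions must sum to 1, got {total}")
        if any(c == "rolled_mulch" for c, _ in zones) and self.termination_date is None:
            raise ValueError("rolled_mulch requires a termination_date")


def _season_envelope(doy: int) -> float:
    """0 in deep winter, 1 on the in-season plateau, linear shoulders."""
    if doy < _SEASON_START or doy > _SEASON_END:
        return 0.0
    if doy < _SEASON_FULL:
        return (doy - _SEASON_START) / (_SEASON_FULL - _SEASON_START)
    if doy > _SEASON_FADE:
        return (_SEASON_END - doy) / (_SEASON_END - _SEASON_FADE)
    return 1.0


def _rolled_rate(days_after: float) -> float:
    offsets = [o for o, _ in ROLLED_ANCHORS]
    rates = [r for _, r in ROLLED_ANCHORS]
    return float(np.interp(days_after, offsets, rates))


def _zone_rate(cover: str, date: dt.date, termination: dt.date | None) -> float:
    doy = date.timetuple().tm_yday
    env = _season_envelope(doy)
    terminated = termination is not None and date >= termination
    if cover == "rolled_mulch" or (cover == "winter_cover_crop" and terminated):
        days_after = (date - termination).days
        rate = _rolled_rate(max(days_after, 0))
        # rolling overrides the seasonal envelope; never below winter baseline
        return max(rate, WINTER_BASELINE_MM)
    peak = SEASON_RATE_MM[cover]
    return WINTER_BASELINE_MM + env * (peak - WINTER_BASELINE_MM)


def ets_daily(floor: FloorManagement, date: dt.date) -> float:
    """Floor (soil + cover) evapotranspiration, mm/day, area-weighted.

    Each zone follows its anchored seasonal curve; every class rests at the
    0.3 mm/day winter baseline.
    """
    return sum(frac * _zone_rate(cover, date, floor.termination_date) for cover, frac in floor.zones)


@dataclass(frozen=True)
class WaterBalanceDay:
    """One day of reservoir state."""

    date: dt.date
    precip_mm: float
    ets_mm: float
    tc_mm: float
    reservoir_mm: float
    saw_pct: float
    warning: str
    drainage_mm: float = 0.0
    unmet_mm: float = 0.0


def step_balance(
    reservoir_mm: float,
    precip_mm: float,
    ets_mm: float,
    tc_mm: float,
    capacity_mm: float,
) -> tuple[float, float, float]:
    """One daily bucket update → (new reservoir, drainage, unmet demand)."""
    for name, v in (("precip", precip_mm), ("ets", ets_mm), ("tc", tc_mm)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if not 0 <= reservoir_mm <= capacity_mm:
        raise ValueError("reservoir outside [0, capacity]")
    raw = reservoir_mm + precip_mm - ets_mm - tc_mm
    drainage = max(raw - capacity_mm, 0.0)
    unmet = max(-raw, 0.0)
    return min(max(raw, 0.0), capacity_mm), drainage, unmet


def classify_warning(saw_pct: float) -> str:
    """Stoplight class for a SAW percentage: green > 60 ≥ yellow > 40 ≥ red."""
    if not 0 <= saw_pct <= 100:
        raise ValueError(f"saw_pct must be in [0, 100], got {saw_pct}")
    if saw_pct > 60:
        return "green"
    if saw_pct > 40:
        return "yellow"
    return "red"


def run_season(
    soil: SoilProfile,
    floor: FloorManagement,
    daily_weather: pd.DataFrame,
    tc_daily_mm: Sequence[float] | pd.Series,
    initial_fill: float = 1.0,
) -> tuple[list[WaterBalanceDay], list[tuple[dt.date, str, str]]]:
    """Run the bucket over a contiguous daily series.

    ``daily_weather`` needs columns (date, precip_mm); ``tc_daily_mm`` is
    the aligned canopy-transpiration series.  The reservoir starts at
    ``initial_fill`` × capacity (full profile at budburst by default,
    reflecting winter recharge).  Returns the per-day records and an
    append-only log of warning transitions (date, from, to).
    """
    dates = [pd.Timestamp(d).date() for d in daily_weather["date"]]
    if len(dates) != len(tc_daily_mm):
        raise ValueError("weather and Tc series lengths differ")
    expected = pd.date_range(dates[0], dates[-1], freq="D").date
    missing = sorted(set(expected) - set(dates))
    if missing:
        raise ValueError(f"gaps in weather series, missing dates: {missing}")
    if not 0 < initial_fill <= 1:
        raise ValueError("initial_fill must be in (0, 1]")

    capacity = soil.saw_capacity_mm
    reservoir = initial_fill * capacity
    records: list[WaterBalanceDay] = []
    transitions: list[tuple[dt.date, str, str]] = []
    prev_warning: str | None = None
    precip = np.asarray(daily_weather["precip_mm"], dtype=float)
    tc = np.asarray(tc_daily_mm, dtype=float)
    for i, date in enumerate(dates):
        ets = ets_daily(floor, date)
        reservoir, drainage, unmet = step_balance(reservoir, precip[i], ets, tc[i], capacity)
        saw = 100.0 * reservoir / capacity
        warning = classify_warning(saw)
        if prev_warning is not None and warning != prev_warning:
            transitions.append((date, prev_warning, warning))
        prev_warning = warning
        records.append(
            WaterBalanceDay(
                date=date,
                precip_mm=float(precip[i]),
                ets_mm=ets,
                tc_mm=float(tc[i]),
                reservoir_mm=reservoir,
                saw_pct=saw,
                warning=warning,
                drainage_mm=drainage,
                unmet_mm=unmet,
            )
        )
    return records, transitions


def balance_frame(records: Iterable[WaterBalanceDay]) -> pd.DataFrame:
    """Tabular view of a season run (export-friendly)."""
    records = list(records)
    return pd.DataFrame(
        {
            "date": [r.date for r in records],
            "precip_mm": [r.precip_mm for r in records],
            "ets_mm": [r.ets_mm for r in records],
            "tc_mm": [r.tc_mm for r in records],
            "reservoir_mm": [r.reservoir_mm for r in records],
            "saw_pct": [r.saw_pct for r in records],
            "warning": [r.warning for r in records],
            "drainage_mm": [r.drainage_mm for r in records],
            "unmet_mm": [r.unmet_mm for r in records],
        }
    )
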