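"""Configuration, file formats and report export.

Weather series travel as delimited text with ISO-8601 dates and a header
naming the required columns; the vineyard descriptor (site, rows, canopy,
soil, floor calendar) is a YAML/JSON document.  Outputs are CSV tables
plus a JSON season summary; drought warnings are exported as an
append-only transition log rather than a per-day dump.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .canopy import VineyardGeometry
from .phenology import STAGE_WINDOWS, StageWindow, daily_vpd
from .water_balance import FloorManagement, SoilProfile, WaterBalanceDay, balance_frame, pedotransfer

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "RunConfig", "read_weather", "load_config", "write_report"]

REQUIRED_WEATHER_COLUMNS = [
    "date",
    "tmin",
    "tmean",
    "tmax",
    "rh_pct",
    "wind",
    "radiation",
    "precip_mm",
]


class SchemaError(ValueError):
    """A file does not carry the columns or fields the schema requires."""


def read_weather(path: str | Path) -> pd.DataFrame:
    """Read, validate and sort a daily weather CSV.

    Required columns: date, tmin, tmean, tmax, rh_pct, wind, radiation
    (MJ m⁻² day⁻¹), precip_mm; optional tsoil.  Adds vpd_kpa when absent,
    attaches a gap report (``frame.attrs["missing_dates"]``), and raises on
    missing columns, unparseable or duplicated dates, or ordering
    violations (tmin ≤ tmean ≤ tmax, RH in [0, 100]).
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"weather file {path} missing required column(s): {missing}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"unparseable date in {path}: {exc}") from exc
    dupes = frame.loc[frame["date"].duplicated(), "date"].tolist()
    if dupes:
        raise SchemaError(
            f"duplicated date(s) in {path}: {sorted(d.isoformat() for d in set(dupes))}"
        )
    frame = frame.sort_values("date").reset_index(drop=True)

    bad_order = frame[(frame["tmin"] > frame["tmean"]) | (frame["tmean"] > frame["tmax"])]
    if not bad_order.empty:
        raise SchemaError(
            f"tmin <= tmean <= tmax violated on: {bad_order['date'].tolist()[:5]}"
        )
    bad_rh = frame[(frame["rh_pct"] < 0) | (frame["rh_pct"] > 100)]
    if not bad_rh.empty:
        raise SchemaError(f"relative humidity outside [0, 100] on: {bad_rh['date'].tolist()[:5]}")

    expected = pd.date_range(frame["date"].iloc[0], frame["date"].iloc[-1], freq="D").date
    gaps = sorted(set(expected) - set(frame["date"]))
    if gaps:
        logger.warning("weather series has %d missing date(s), first: %s", len(gaps), gaps[0])
    frame.attrs["missing_dates"] = gaps
    if "vpd_kpa" not in frame.columns:
        frame["vpd_kpa"] = daily_vpd(frame["tmean"], frame["rh_pct"])
    return frame


@dataclass(frozen=True)
class RunConfig:
    """Everything a season run needs, loaded from one YAML/JSON document."""

    geometry: VineyardGeometry
    soil: SoilProfile
    floor: FloorManagement
    weather_path: Path | None
    stage_windows: dict[str, StageWindow]
    extraction_threshold: float
    seed: int
    output_dir: Path


def load_config(path: str | Path) -> RunConfig:
    """Parse the vineyard/run configuration (YAML or JSON)."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    try:
        g = doc["vineyard"]
        geometry = VineyardGeometry(
            latitude=g["latitude"],
            longitude=g.get("longitude", 0.0),
            altitude=g.get("altitude", 0.0),
            row_azimuth=g["row_azimuth"],
            row_spacing=g["row_spacing"],
            canopy_height=g["canopy_height"],
            canopy_width=g["canopy_width"],
            canopy_base_height=g.get("canopy_base_height", 0.6),
            slope=g.get("slope", 0.0),
            aspect=g.get("aspect", 0.0),
        )
        s = doc["soil"]
        soil = pedotransfer(
            s["sand_pct"], s["clay_pct"], s["om_pct"], s.get("depth_m", 1.0)
        )
        f = doc["floor"]
        termination = f.get("termination_date")
        if isinstance(termination, str):
            termination = dt.date.fromisoformat(termination)
        floor = FloorManagement(
            zones=tuple((z["cover"], z["fraction"]) for z in f["zones"]),
            termination_date=termination,
        )
    except KeyError as exc:
        raise SchemaError(f"config {path} missing required field: {exc}") from exc

    windows = dict(STAGE_WINDOWS)
    for stage, bounds in doc.get("stage_windows", {}).items():
        windows[stage] = StageWindow(stage, bounds[0], bounds[1])
    weather = doc.get("weather_path")
    if weather is not None:
        weather = Path(weather)
        if not weather.is_absolute():
            weather = Path(path).parent / weather
        if not weather.exists():
            raise SchemaError(f"config {path}: weather file {weather} does not exist")
    return RunConfig(
        geometry=geometry,
        soil=soil,
        floor=floor,
        weather_path=weather,
        stage_windows=windows,
        extraction_threshold=float(doc.get("extraction_threshold", 0.5)),
        seed=int(doc.get("seed", 0)),
        output_dir=Path(doc.get("output_dir", ".")),
    )


def write_report(
    out_dir: str | Path,
    balance_days: list[WaterBalanceDay],
    transitions: list[tuple[dt.date, str, str]],
    phenology_predictions: dict[str, int | None] | None = None,
    water_use_totals: dict[str, float] | None = None,
) -> dict:
    """Season summary: machine-readable tables + JSON digest.

    Writes ``balance.csv`` (per-day state), ``warnings.csv`` (transition
    log) and ``summary.json``; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = balance_frame(balance_days)
    frame.to_csv(out / "balance.csv", index=False)
    pd.DataFrame(transitions, columns=["date", "from", "to"]).to_csv(
        out / "warnings.csv", index=False
    )
    worst = "green"
    for day in balance_days:
        if day.warning == "red":
            worst = "red"
            break
        if day.warning == "yellow":
            worst = "yellow"
    summary = {
        "period": {
            "start": balance_days[0].date.isoformat(),
            "end": balance_days[-1].date.isoformat(),
        },
        "all_green": not transitions and worst == "green",
        "worst_warning": worst,
        "warning_transitions": [
            {"date": d.isoformat(), "from": a, "to": b} for d, a, b in transitions
        ],
        "final_saw_pct": balance_days[-1].saw_pct,
        "total_precip_mm": float(frame["precip_mm"].sum()),
        "total_ets_mm": float(frame["ets_mm"].sum()),
        "total_tc_mm": float(frame["tc_mm"].sum()),
        "phenology_predictions": phenology_predictions or {},
        "water_use_totals": water_use_totals or {},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
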