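"""Canopy-transpiration regression and water-use unit conversions.

Whole-canopy vine transpiration T_c (mmol H₂O s⁻¹) is regressed on three
drivers: x1 = incoming direct light (µmol m⁻² s⁻¹), x2 = air vapour
pressure deficit (hPa) and x3 = total canopy light interception (TCLI, %).
The operational form is an intercept-free quadratic with exactly the six
terms

    y = a·x1² + b·x2² + c·x3² + d·x1·x2 + e·x1·x3 + f·x2·x3

so the prediction at (0, 0, 0) — no light, saturated air, no interception —
is exactly zero.  Linear variants and reduced variable subsets are kept for
model comparison.

VPD enters in hPa; kilopascal inputs must be converted at the boundary
(1 kPa = 10 hPa).  All downstream unit conversions (g h⁻¹, L vine⁻¹ day⁻¹,
mm day⁻¹, L m⁻² leaf) are centralised here.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TcModel",
    "TcObservation",
    "DailyWaterUse",
    "UnderdeterminedFitError",
    "fit_tc_model",
    "predict_tc",
    "convert_rate",
    "daily_totals",
    "compare_tc_models",
    "tc_series",
    "CALIBRATED_MODELS",
    "WATER_MOLAR_MASS_G",
]

#: Molar mass of water, g mol⁻¹.
WATER_MOLAR_MASS_G = 18.015

VARIABLES = ("x1", "x2", "x3")


class UnderdeterminedFitError(ValueError):
    """Raised when the design matrix cannot identify all model terms."""


def _quadratic_terms(variables: Sequence[str]) -> list[str]:
    squares = [f"{v}^2" for v in variables]
    crosses = [f"{a}*{b}" for a, b in itertools.combinations(variables, 2)]
    return squares + crosses


def _linear_terms(variables: Sequence[str]) -> list[str]:
    return ["1"] + list(variables)


@dataclass(frozen=True)
class TcObservation:
    """One timed canopy-transpiration reading with its drivers."""

    time: object
    x1: float  # direct light, µmol m⁻² s⁻¹
    x2: float  # air VPD, hPa
    x3: float  # TCLI, %
    y: float  # measured T_c, mmol H₂O s⁻¹

    def __post_init__(self) -> None:
        if not 0.0 <= self.x3 <= 100.0:
            raise ValueError(f"TCLI must be in [0, 100] %, got {self.x3}")
        if self.x1 < 0 or self.y < 0:
            raise ValueError("light and transpiration must be >= 0")


@dataclass(frozen=True)
class TcModel:
    """Fitted (or published) transpiration model.

    ``coefficients`` maps term names ("x1^2", "x1*x2", ... for quadratic;
    "1", "x1", ... for linear) to values; absent terms are zero.
    """

    form: str  # "linear" | "quadratic"
    variables: tuple[str, ...]
    coefficients: dict[str, float]
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        bad = set(self.variables) - set(VARIABLES)
        if bad or not self.variables:
            raise ValueError(f"variables must be a non-empty subset of {VARIABLES}")
        object.__setattr__(self, "variables", tuple(self.variables))

    @property
    def term_names(self) -> list[str]:
        if self.form == "quadratic":
            return _quadratic_terms(self.variables)
        return _linear_terms(self.variables)

    def to_json(self) -> str:
        return json.dumps(
            {
                "form": self.form,
                "variables": list(self.variables),
                "coefficients": self.coefficients,
                "r_squared": self.r_squared,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TcModel":
        d = json.loads(text)
        return cls(
            form=d["form"],
            variables=tuple(d["variables"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            r_squared=d.get("r_squared"),
        )


def _as_frame(observations: Iterable[TcObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        missing = {"x1", "x2", "x3", "y"} - set(observations.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        return observations
    rows = [(o.x1, o.x2, o.x3, o.y) for o in observations]
    return pd.DataFrame(rows, columns=["x1", "x2", "x3", "y"])


def _eval_term(term: str, values: dict[str, np.ndarray]) -> np.ndarray:
    if term == "1":
        some = next(iter(values.values()))
        return np.ones_like(some, dtype=float)
    if term.endswith("^2"):
        v = values[term[:-2]]
        return v * v
    if "*" in term:
        a, b = term.split("*")
        return values[a] * values[b]
    return values[term]


def _design_matrix(frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    values = {v: frame[v].to_numpy(dtype=float) for v in VARIABLES if v in frame}
    return np.column_stack([_eval_term(t, values) for t in terms])


def fit_tc_model(
    observations: Iterable[TcObservation] | pd.DataFrame,
    form: str = "quadratic",
    variables: Sequence[str] = VARIABLES,
) -> TcModel:
    """Least-squares fit of the transpiration model.

    Raises :class:`UnderdeterminedFitError` when there are fewer
    observations than terms or the design is rank deficient.
    """
    frame = _as_frame(observations)
    proto = TcModel(form=form, variables=tuple(variables), coefficients={})
    terms = proto.term_names
    design = _design_matrix(frame, terms)
    y = frame["y"].to_numpy(dtype=float)
    if design.shape[0] < len(terms):
        raise UnderdeterminedFitError(
            f"{design.shape[0]} observations cannot identify {len(terms)} terms"
        )
    if np.linalg.matrix_rank(design) < len(terms):
        raise UnderdeterminedFitError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TcModel(
        form=form,
        variables=tuple(variables),
        coefficients=dict(zip(terms, (float(c) for c in coef))),
        r_squared=max(0.0, min(1.0, r2)),
    )


def predict_tc(model: TcModel, x1, x2, x3, clamp_negative: bool = True):
    """Evaluate the model; negative raw predictions clamp to 0 (logged).

    Accepts scalars or arrays; returns the matching shape.
    """
    values = {
        "x1": np.asarray(x1, dtype=float),
        "x2": np.asarray(x2, dtype=float),
        "x3": np.asarray(x3, dtype=float),
    }
    used = set("".join(model.variables))
    for v in model.variables:
        if v not in values:
            raise ValueError(f"model requires variable {v}")
    del used
    y = np.zeros(np.broadcast(values["x1"], values["x2"], values["x3"]).shape, dtype=float)
    for term, coef in model.coefficients.items():
        y = y + coef * _eval_term(term, values)
    if clamp_negative:
        neg = y < 0
        if np.any(neg):
            logger.warning(
                "clamped %d negative transpiration prediction(s) to zero", int(np.sum(neg))
            )
            y = np.where(neg, 0.0, y)
    if np.ndim(x1) == 0 and np.ndim(x2) == 0 and np.ndim(x3) == 0:
        return float(y)
    return y


def convert_rate(y_mmol_per_s: float) -> float:
    """mmol H₂O s⁻¹ → g h⁻¹ (1 mmol s⁻¹ = 64.854 g h⁻¹)."""
    if np.any(np.asarray(y_mmol_per_s) < 0):
        raise ValueError("transpiration rate must be >= 0")
    return y_mmol_per_s * WATER_MOLAR_MASS_G * 3600.0 / 1000.0


@dataclass(frozen=True)
class DailyWaterUse:
    """Daily canopy water use on per-vine, per-area and per-leaf bases."""

    litres_per_vine: float
    mm_per_day: float
    litres_per_m2_leaf: float


def daily_totals(
    mean_rate_g_per_h: float,
    day_length_h: float,
    density_per_ha: float = 4000.0,
    leaf_area_m2: float = 3.37,
) -> DailyWaterUse:
    """Scale a dawn-to-dusk mean rate to daily totals.

    litres/vine = rate × day length / 1000; mm/day spreads the per-vine
    volume over the vine's ground share (density/ha / 10 000 m²);
    L m⁻² divides by the vine leaf area.
    """
    if min(mean_rate_g_per_h, day_length_h, density_per_ha, leaf_area_m2) <= 0:
        raise ValueError("all inputs must be > 0")
    litres = mean_rate_g_per_h * day_length_h / 1000.0
    return DailyWaterUse(
        litres_per_vine=litres,
        mm_per_day=litres * density_per_ha / 10_000.0,
        litres_per_m2_leaf=litres / leaf_area_m2,
    )


def compare_tc_models(
    observations: Iterable[TcObservation] | pd.DataFrame,
) -> pd.DataFrame:
    """Fit every form × variable-subset candidate; rank by R².

    Returns a table (form, variables, r_squared, error, best); candidates
    whose fit fails carry the error message instead of aborting the sweep.
    """
    frame = _as_frame(observations)
    rows = []
    for form in ("linear", "quadratic"):
        for k in (1, 2, 3):
            for combo in itertools.combinations(VARIABLES, k):
                try:
                    model = fit_tc_model(frame, form=form, variables=combo)
                    rows.append(
                        {
                            "form": form,
                            "variables": "+".join(combo),
                            "r_squared": model.r_squared,
                            "error": "",
                        }
                    )
                except UnderdeterminedFitError as exc:
                    rows.append(
                        {"form": form, "variables": "+".join(combo), "r_squared": np.nan, "error": str(exc)}
                    )
    table = pd.DataFrame(rows)
    table["best"] = False
    if table["r_squared"].notna().any():
        table.loc[table["r_squared"].idxmax(), "best"] = True
    return table


def tc_series(
    model: TcModel,
    tcli_profile: pd.DataFrame,
    weather_subdaily: pd.DataFrame,
    density_per_ha: float = 4000.0,
) -> tuple[pd.DataFrame, float]:
    """Predict T_c on a sub-daily grid and integrate the day, in mm.

    ``tcli_profile`` needs columns (time, tcli_percent); ``weather_subdaily``
    needs (time, direct_light, vpd_hpa) on the *same* solar-time grid.
    Returns (per-instant series, daily total in mm via trapezoidal
    integration over daylight and the vine-density ground share).
    """
    t1 = np.asarray(tcli_profile["time"], dtype=float)
    t2 = np.asarray(weather_subdaily["time"], dtype=float)
    if len(t1) != len(t2) or not np.allclose(t1, t2, atol=1e-6):
        raise ValueError("tcli profile and weather grids are not aligned")
    y = predict_tc(
        model,
        weather_subdaily["direct_light"].to_numpy(dtype=float),
        weather_subdaily["vpd_hpa"].to_numpy(dtype=float),
        tcli_profile["tcli_percent"].to_numpy(dtype=float),
    )
    series = pd.DataFrame({"time": t1, "tc_mmol_s": y})
    if len(t1) < 2:
        grams = 0.0
    else:
        # mmol/s integrated over seconds → mol → grams of water per vine
        mmol = float(np.trapezoid(y, t1 * 3600.0))
        grams = mmol / 1000.0 * WATER_MOLAR_MASS_G
    litres = grams / 1000.0
    mm = litres * density_per_ha / 10_000.0
    return series, mm


def _quadratic_coeffs(a, b, c, d, e, f) -> dict[str, float]:
    return {
        "x1^2": a,
        "x2^2": b,
        "x3^2": c,
        "x1*x2": d,
        "x1*x3": e,
        "x2*x3": f,
    }


#: Published day-specific quadratic calibrations (x1 = direct light µmol
#: m⁻² s⁻¹, x2 = VPD hPa, x3 = TCLI %).  The "2022-08-01" source equation
#: ends with two x1·x2 terms — stored verbatim (last coefficient folded
#: onto x1·x2) alongside a corrected variant that reads the final term as
#: x2·x3, the canonical sixth term.
CALIBRATED_MODELS: dict[str, TcModel] = {
    "2022-06-20": TcModel(
        form="quadratic",
        variables=VARIABLES,
        coefficients=_quadratic_coeffs(
            7.62563e-09, 0.0104358, 1.49096e-06, -7.72001e-06, 1.07106e-07, -0.000129436
        ),
        r_squared=0.96,
    ),
    "2022-07-02": TcModel(
        form="quadratic",
        variables=VARIABLES,
        coefficients=_quadratic_coeffs(
            -2.88612e-08, -0.0038447, -3.08502e-06, 4.12417e-05, -7.19364e-07, 0.00044962
        ),
        r_squared=0.93,
    ),
    "2022-08-01-as-published": TcModel(
        form="quadratic",
        variables=VARIABLES,
        coefficients=_quadratic_coeffs(
            -5.0084e-09, 0.00716466, 4.62933e-06, -2.40068e-06 + -0.000160624, 1.60601e-07, 0.0
        ),
        r_squared=0.98,
    ),
    "2022-08-01-corrected": TcModel(
        form="quadratic",
        variables=VARIABLES,
        coefficients=_quadratic_coeffs(
            -5.0084e-09, 0.00716466, 4.62933e-06, -2.40068e-06, 1.60601e-07, -0.000160624
        ),
        r_squared=0.98,
    ),
}
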