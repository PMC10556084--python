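"""Windowed binary-event phenology prediction.

Budburst, flowering and veraison are predicted by casting each day inside a
stage-specific calendar window (budburst DOY 65–100, flowering 140–175,
veraison 190–230) as a binary outcome: 1 on the day the stage was observed
for that site-year, 0 otherwise.  Daily weather features — thermal time
(GDD base 10 °C), cumulated radiation and reference evapotranspiration,
temperatures, VPD, humidity, wind, precipitation — feed a pluggable
classifier (gradient-boosted trees by default, with random-forest,
support-vector and k-nearest-neighbour baselines).  Predicted event dates
are the rounded mean of all above-threshold days inside the window, and
prediction skill is scored as RMSE in days.

Class imbalance (one positive day against ~35 negatives per site-year) is
handled by seeded over-/under-sampling of the training partition only,
after the train/test split, so no resampled copy of a test row can leak
into training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "StageWindow",
    "STAGE_WINDOWS",
    "EvalMetrics",
    "cumulative_gdd",
    "daily_vpd",
    "reference_etp",
    "build_features",
    "correlation_screen",
    "assemble_binary",
    "rebalance",
    "split_train_test",
    "loocv",
    "evaluate",
    "extract_event_date",
    "rmse_days",
    "make_classifier",
    "predict_site_year_dates",
    "benchmark_table",
    "GDD_BASE_C",
]

GDD_BASE_C = 10.0

FEATURE_COLUMNS = [
    "cum_gdd",
    "cum_radiation",
    "cum_etp",
    "tmax",
    "tmean",
    "tsoil",
    "vpd_kpa",
    "rh_pct",
    "wind",
    "precip_mm",
]


@dataclass(frozen=True)
class StageWindow:
    """Calendar window (DOY, inclusive) in which a stage may be declared."""

    stage: str
    doy_start: int
    doy_end: int

    def __post_init__(self) -> None:
        if not self.doy_start < self.doy_end:
            raise ValueError("window start must precede end")

    def contains(self, doy: int) -> bool:
        return self.doy_start <= doy <= self.doy_end

    @property
    def doys(self) -> np.ndarray:
        return np.arange(self.doy_start, self.doy_end + 1)


STAGE_WINDOWS: dict[str, StageWindow] = {
    "budburst": StageWindow("budburst", 65, 100),
    "flowering": StageWindow("flowering", 140, 175),
    "veraison": StageWindow("veraison", 190, 230),
}


def cumulative_gdd(
    tmean: Sequence[float] | pd.Series, base_c: float = GDD_BASE_C
) -> np.ndarray:
    """Cumulative growing degree days: Σ max(0, Tmean − base).

    The series is assumed to start 1 January and be contiguous; gap
    checking against dates belongs to the weather reader.
    """
    t = np.asarray(tmean, dtype=float)
    return np.cumsum(np.maximum(t - base_c, 0.0))


def saturation_vapour_pressure(t_c) -> np.ndarray:
    """Tetens saturation vapour pressure (kPa) over water."""
    t = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def daily_vpd(tmean, rh_pct):
    """Daily vapour pressure deficit (kPa) from mean T and RH (Tetens)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100] %")
    out = saturation_vapour_pressure(tmean) * (1.0 - rh / 100.0)
    return float(out) if np.ndim(tmean) == 0 and np.ndim(rh_pct) == 0 else out


def _extraterrestrial_radiation_mj(latitude: float, doy) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m⁻² day⁻¹), FAO-56 eq. 21."""
    doy = np.asarray(doy, dtype=float)
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (
        24.0 * 60.0 / np.pi * 0.0820 * dr
        * (ws * math.sin(phi) * np.sin(delta) + math.cos(phi) * np.cos(delta) * np.sin(ws))
    )


def reference_etp(
    tmin,
    tmax,
    rh_pct,
    wind_2m,
    radiation_mj,
    latitude: float,
    doy,
    altitude_m: float = 0.0,
):
    """Daily FAO-56 Penman–Monteith reference evapotranspiration (mm/day).

    Inputs: daily min/max air temperature (°C), mean relative humidity (%),
    wind speed at 2 m (m s⁻¹) and measured global radiation
    (MJ m⁻² day⁻¹).  Actual vapour pressure comes from mean RH applied to
    the mean of the saturation pressures at Tmax and Tmin; soil heat flux
    is neglected at the daily step.  Negative results (rare, strongly
    advective nights) clamp to zero.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = (tmin + tmax) / 2.0
    rs = np.asarray(radiation_mj, dtype=float)
    u2 = np.asarray(wind_2m, dtype=float)

    es = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    ea = es * np.asarray(rh_pct, dtype=float) / 100.0
    delta = 4098.0 * saturation_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * altitude_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    ra = _extraterrestrial_radiation_mj(latitude, doy)
    rso = (0.75 + 2e-5 * altitude_m) * ra
    rns = (1.0 - 0.23) * rs
    sigma = 4.903e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.clip(np.where(rso > 0, rs / rso, 0.0), 0.0, 1.0)
    rnl = (
        sigma
        * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * np.maximum(1.35 * rel - 0.35, 0.0)  # overcast floor: no longwave gain
    )
    rn = rns - rnl
    et0 = (
        0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    ) / (delta + gamma * (1.0 + 0.34 * u2))
    out = np.maximum(et0, 0.0)
    return float(out) if np.ndim(tmin) == 0 else out


def build_features(weather: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Daily as-of-date feature table from a one-year weather frame.

    Expects columns date, tmin, tmean, tmax, rh_pct, wind, radiation,
    precip_mm and optionally tsoil (fallback: 5-day lagged rolling mean of
    tmean, a crude soil thermal buffer).  Cumulative features (GDD,
    radiation, reference ET) accumulate from the first row, which should be
    1 January.
    """
    w = weather.reset_index(drop=True)
    doy = pd.DatetimeIndex(pd.to_datetime(w["date"])).dayofyear.to_numpy()
    feats = pd.DataFrame({"date": w["date"], "doy": doy})
    feats["cum_gdd"] = cumulative_gdd(w["tmean"])
    feats["cum_radiation"] = np.cumsum(w["radiation"].to_numpy(dtype=float))
    etp = reference_etp(
        w["tmin"], w["tmax"], w["rh_pct"], w["wind"], w["radiation"], latitude, doy
    )
    feats["cum_etp"] = np.cumsum(etp)
    feats["tmax"] = w["tmax"].astype(float)
    feats["tmean"] = w["tmean"].astype(float)
    if "tsoil" in w.columns and w["tsoil"].notna().all():
        feats["tsoil"] = w["tsoil"].astype(float)
    else:
        feats["tsoil"] = (
            w["tmean"].rolling(5, min_periods=1).mean().shift(1).bfill().astype(float)
        )
    feats["vpd_kpa"] = daily_vpd(w["tmean"], w["rh_pct"])
    feats["rh_pct"] = w["rh_pct"].astype(float)
    feats["wind"] = w["wind"].astype(float)
    feats["precip_mm"] = w["precip_mm"].astype(float)
    return feats


def correlation_screen(
    feature_table: pd.DataFrame,
    event_doys: Sequence[float] | pd.Series,
    cutoff: float = 0.3,
) -> tuple[list[str], pd.Series]:
    """Pearson screen of site-year features against the event DOY.

    ``feature_table`` holds one row per site-year (feature values taken at
    the observed event date).  Features with |r| > cutoff are retained;
    zero-variance features are dropped with a warning.
    """
    y = np.asarray(event_doys, dtype=float)
    if len(feature_table) != len(y):
        raise ValueError("feature table and event DOYs differ in length")
    if len(y) < 3:
        raise ValueError("need at least 3 site-years for the screen")
    rs = {}
    for col in feature_table.columns:
        if col in ("site_year", "date", "doy"):
            continue
        x = feature_table[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"feature {col!r} has zero variance; dropped from screen")
            continue
        rs[col] = float(np.corrcoef(x, y)[0, 1])
    r = pd.Series(rs, name="r")
    retained = [name for name, val in r.items() if abs(val) > cutoff]
    return retained, r


def assemble_binary(
    features_by_day: pd.DataFrame,
    events: Mapping[str, int],
    window: StageWindow,
) -> pd.DataFrame:
    """Per-day binary dataset for one stage window.

    ``features_by_day`` has columns (site_year, doy, <features>); ``events``
    maps site-year id → observed event DOY.  One row per in-window day per
    site-year, labelled 1 on the event day only.  Site-years whose event
    falls outside the window are excluded with a warning.
    """
    rows = []
    for site_year, event_doy in events.items():
        if not window.contains(int(event_doy)):
            warnings.warn(
                f"site-year {site_year!r}: event DOY {event_doy} outside "
                f"{window.stage} window [{window.doy_start}, {window.doy_end}]; excluded"
            )
            continue
        block = features_by_day[
            (features_by_day["site_year"] == site_year)
            & features_by_day["doy"].between(window.doy_start, window.doy_end)
        ].copy()
        block["label"] = (block["doy"] == int(event_doy)).astype(int)
        rows.append(block)
    if not rows:
        raise ValueError("no site-year has its event inside the window")
    return pd.concat(rows, ignore_index=True)


def rebalance(
    dataset: pd.DataFrame,
    strategy: str = "oversample",
    target_ratio: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded class rebalancing toward positives:negatives = target_ratio.

    ``oversample`` duplicates positive rows with replacement; ``undersample``
    drops negative rows without replacement.  Deterministic under a fixed
    seed.
    """
    if strategy not in ("oversample", "undersample"):
        raise ValueError(f"unknown strategy {strategy!r}")
    pos = dataset[dataset["label"] == 1]
    neg = dataset[dataset["label"] == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("rebalance requires both classes present")
    rng = np.random.default_rng(seed)
    if strategy == "oversample":
        n_target = int(round(target_ratio * len(neg)))
        extra = rng.choice(pos.index.to_numpy(), size=max(n_target - len(pos), 0), replace=True)
        out = pd.concat([dataset, dataset.loc[extra]], ignore_index=True)
    else:
        n_keep = int(round(len(pos) / target_ratio))
        keep = rng.choice(neg.index.to_numpy(), size=min(n_keep, len(neg)), replace=False)
        out = pd.concat([pos, neg.loc[np.sort(keep)]], ignore_index=True)
    return out


def split_train_test(
    dataset: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    group_col: str | None = None,
    n_test_groups: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded train/test split, row-wise or holding out whole groups.

    Row-wise: ⌈ratio·n⌉ training rows.  Grouped (``group_col`` set): whole
    groups (site-years) go to the test side — ``n_test_groups`` of them, or
    the count closest to the ratio.
    """
    rng = np.random.default_rng(seed)
    if group_col is None:
        if len(dataset) < 5:
            raise ValueError("need at least 5 rows to split")
        idx = rng.permutation(len(dataset))
        n_train = math.ceil(ratio * len(dataset))
        train = dataset.iloc[np.sort(idx[:n_train])].reset_index(drop=True)
        test = dataset.iloc[np.sort(idx[n_train:])].reset_index(drop=True)
        return train, test
    groups = dataset[group_col].unique()
    if n_test_groups is None:
        n_test_groups = max(1, int(round((1.0 - ratio) * len(groups))))
    held_out = rng.choice(groups, size=n_test_groups, replace=False)
    mask = dataset[group_col].isin(held_out)
    return dataset[~mask].reset_index(drop=True), dataset[mask].reset_index(drop=True)


def loocv(
    dataset: pd.DataFrame,
    learner,
    feature_cols: Sequence[str],
    label_col: str = "label",
) -> tuple[np.ndarray, list[int]]:
    """Leave-one-out cross-validation scores.

    Fold i fits a clone of ``learner`` on all rows but i and scores row i
    (positive-class probability, or decision value rescaled, or the bare
    prediction, in that order of preference).  Failed folds are recorded
    and reported, not fatal; their score is NaN.
    """
    if len(dataset) < 2:
        raise ValueError("LOOCV needs at least 2 rows")
    x = dataset[list(feature_cols)].to_numpy(dtype=float)
    y = dataset[label_col].to_numpy()
    scores = np.full(len(dataset), np.nan)
    failures: list[int] = []
    for i in range(len(dataset)):
        mask = np.ones(len(dataset), dtype=bool)
        mask[i] = False
        model = clone(learner)
        try:
            model.fit(x[mask], y[mask])
            scores[i] = _positive_score(model, x[i : i + 1])[0]
        except Exception:
            failures.append(i)
    return scores, failures


def _positive_score(model, x) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(x)
        classes = list(getattr(model, "classes_", [0, 1]))
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(len(x))
    if hasattr(model, "decision_function"):
        d = model.decision_function(x)
        return 1.0 / (1.0 + np.exp(-d))
    return model.predict(x).astype(float)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and derived classification scores.

    ``auc`` is None when the labels hold a single class.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float | None
    rmse_days: float | None = None


def evaluate(scores, labels, threshold: float = 0.5) -> EvalMetrics:
    """Confusion-matrix metrics at a threshold plus threshold-free AUC.

    precision = TP/(TP+FP); recall = TP/(TP+FN); accuracy = (TP+TN)/n;
    F1 = TP/(TP + (FP+FN)/2).  Undefined ratios (empty denominators)
    report 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in shape")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / len(y) if len(y) else 0.0
    f1 = tp / (tp + 0.5 * (fp + fn)) if tp + 0.5 * (fp + fn) else 0.0
    auc = float(roc_auc_score(y, s)) if len(np.unique(y)) == 2 else None
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, precision=precision, recall=recall, accuracy=accuracy, f1=f1, auc=auc)


def extract_event_date(
    daily_probabilities: pd.DataFrame | pd.Series,
    window: StageWindow,
    threshold: float = 0.5,
) -> int | None:
    """Predicted event DOY from daily positive-class probabilities.

    All in-window days whose probability exceeds the threshold vote; the
    prediction is their mean DOY rounded to the nearest whole day, or None
    when no day qualifies (no sufficiently reliable prediction).
    """
    if isinstance(daily_probabilities, pd.Series):
        doys = daily_probabilities.index.to_numpy(dtype=float)
        probs = daily_probabilities.to_numpy(dtype=float)
    else:
        doys = daily_probabilities["doy"].to_numpy(dtype=float)
        probs = daily_probabilities["probability"].to_numpy(dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mask = (doys >= window.doy_start) & (doys <= window.doy_end) & (probs > threshold)
    if not np.any(mask):
        return None
    return int(round(float(np.mean(doys[mask]))))


def threshold_sweep(
    probabilities_by_site_year: Mapping[str, pd.DataFrame],
    observed: Mapping[str, int],
    window: StageWindow,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2)),
) -> pd.DataFrame:
    """RMSE-days and coverage as the extraction threshold varies.

    Helps pick the reliability threshold the date extraction needs; rows
    with no prediction at a given threshold count against coverage, not
    RMSE.
    """
    rows = []
    for th in thresholds:
        preds = [
            extract_event_date(probabilities_by_site_year[sy], window, th)
            for sy in observed
        ]
        obs = [observed[sy] for sy in observed]
        try:
            rmse, excluded = rmse_days(preds, obs)
        except ValueError:
            rmse, excluded = np.nan, len(obs)
        rows.append(
            {
                "threshold": th,
                "rmse_days": rmse,
                "coverage": 1.0 - excluded / len(obs),
            }
        )
    return pd.DataFrame(rows)


def rmse_days(
    predicted_doys: Sequence[int | None], observed_doys: Sequence[int]
) -> tuple[float, int]:
    """Root-mean-square error in days over the predicted pairs.

    No-prediction entries (None) are excluded and counted; an empty pairing
    is an error.  Returns (rmse, n_excluded).
    """
    if len(predicted_doys) != len(observed_doys):
        raise ValueError("prediction and observation lists differ in length")
    pairs = [(p, o) for p, o in zip(predicted_doys, observed_doys) if p is not None]
    excluded = len(predicted_doys) - len(pairs)
    if not pairs:
        raise ValueError("no predictions to score")
    diffs = np.array([p - o for p, o in pairs], dtype=float)
    return float(np.sqrt(np.mean(diffs**2))), excluded


def make_classifier(name: str = "xgboost", seed: int = 0):
    """Benchmark learners: xgboost | random_forest | svm | knn."""
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=120,
            max_depth=3,
            learning_rate=0.2,
            subsample=0.9,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(probability=True, random_state=seed))
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    raise ValueError(f"unknown classifier {name!r}")


def predict_site_year_dates(
    model,
    dataset: pd.DataFrame,
    feature_cols: Sequence[str],
    window: StageWindow,
    threshold: float = 0.5,
) -> dict[str, int | None]:
    """Per-site-year event dates from a fitted classifier.

    ``dataset`` holds the (unresampled) in-window rows of the site-years to
    score.
    """
    out: dict[str, int | None] = {}
    for site_year, block in dataset.groupby("site_year", sort=True):
        probs = _positive_score(model, block[list(feature_cols)].to_numpy(dtype=float))
        frame = pd.DataFrame({"doy": block["doy"].to_numpy(), "probability": np.clip(probs, 0, 1)})
        out[str(site_year)] = extract_event_date(frame, window, threshold)
    return out


def run_stage_harness(
    site_years: Sequence[Mapping],
    stage: str,
    seed: int = 0,
    classifier: str = "xgboost",
    threshold: float = 0.5,
    cutoff: float = 0.3,
) -> dict:
    """Full pipeline for one stage over prepared site-years.

    Each entry in ``site_years`` carries ``site_year`` (id), ``weather``
    (daily frame from 1 January), ``latitude`` and ``events`` (stage →
    observed DOY).  Steps: daily features → correlation screen on
    window-start aggregates → windowed binary assembly → grouped 80:20
    split → oversampling of the training side → classifier → per-site-year
    date extraction → RMSE-days on the held-out site-years.

    Returns a dict with the screen series ``r``, ``retained`` features,
    ``rmse_days``, ``n_no_prediction``, ``n_test`` and the per-site-year
    ``predictions``.
    """
    window = STAGE_WINDOWS[stage]
    frames = []
    events: dict[str, int] = {}
    for sy in site_years:
        ev = sy["events"].get(stage)
        if ev is None:
            continue
        feats = build_features(sy["weather"], sy["latitude"])
        feats.insert(0, "site_year", sy["site_year"])
        frames.append(feats)
        events[sy["site_year"]] = int(ev)
    features = pd.concat(frames, ignore_index=True)

    # screen on per-site-year feature states at the window opening: the
    # event date is unknown at prediction time, the window start is not
    agg_rows = []
    for site_year in events:
        block = features[
            (features["site_year"] == site_year) & (features["doy"] == window.doy_start)
        ]
        agg_rows.append(block[FEATURE_COLUMNS].iloc[0])
    agg = pd.DataFrame(agg_rows).reset_index(drop=True)
    retained, r = correlation_screen(agg, list(events.values()), cutoff)
    if not retained:
        retained = list(r.abs().sort_values(ascending=False).index[:3])

    dataset = assemble_binary(features, events, window)
    train, test = split_train_test(dataset, seed=seed, group_col="site_year")
    balanced = rebalance(train, "oversample", seed=seed)
    learner = make_classifier(classifier, seed=seed)
    learner.fit(balanced[retained].to_numpy(dtype=float), balanced["label"].to_numpy())
    predictions = predict_site_year_dates(learner, test, retained, window, threshold)
    observed = [events[k] for k in predictions]
    try:
        rmse, excluded = rmse_days(list(predictions.values()), observed)
    except ValueError:
        rmse, excluded = float("nan"), len(observed)
    return {
        "stage": stage,
        "r": r,
        "retained": retained,
        "rmse_days": rmse,
        "n_no_prediction": excluded,
        "n_test": len(predictions),
        "predictions": predictions,
        "events": events,
        "model": learner,
    }


def benchmark_table(results: Mapping[tuple[str, str, str], EvalMetrics]) -> pd.DataFrame:
    """Flatten {(model, stage, split): metrics} into a benchmark table.

    Layout: one row per model × stage × split with AUC, accuracy, recall,
    precision, F1 and RMSE-days columns.
    """
    rows = []
    for (model_name, stage, split), m in results.items():
        rows.append(
            {
                "model": model_name,
                "stage": stage,
                "split": split,
                "auc": m.auc,
                "accuracy": m.accuracy,
                "recall": m.recall,
                "precision": m.precision,
                "f1": m.f1,
                "rmse_days": m.rmse_days,
            }
        )
    return pd.DataFrame(rows)
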