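"""Feature construction, screening, resampling, metrics and date extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from vinecast.phenology import (
    STAGE_WINDOWS,
    StageWindow,
    assemble_binary,
    build_features,
    correlation_screen,
    cumulative_gdd,
    daily_vpd,
    evaluate,
    extract_event_date,
    loocv,
    make_classifier,
    rebalance,
    reference_etp,
    rmse_days,
    split_train_test,
)


class TestGdd:
    def test_clamped_accumulation(self):
        assert list(cumulative_gdd([12.0, 8.0, 15.0])) == [2.0, 2.0, 7.0]

    def test_all_below_base_accumulates_nothing(self):
        assert cumulative_gdd(np.full(50, 9.0)).max() == 0.0

    def test_linear_above_base(self):
        assert cumulative_gdd(np.full(100, 11.0))[-1] == pytest.approx(100.0)

    def test_non_decreasing(self, rng):
        series = cumulative_gdd(rng.uniform(-5, 30, 365))
        assert (np.diff(series) >= 0).all()


class TestVpd:
    def test_saturated_air_has_no_deficit(self):
        assert daily_vpd(20.0, 100.0) == pytest.approx(0.0)

    def test_dry_air_equals_saturation_pressure(self):
        assert daily_vpd(25.0, 0.0) == pytest.approx(3.1678, abs=2e-3)

    def test_tetens_midpoint(self):
        assert daily_vpd(25.0, 50.0) == pytest.approx(1.58, abs=0.02)

    def test_invalid_humidity_rejected(self):
        with pytest.raises(ValueError):
            daily_vpd(20.0, 120.0)


class TestReferenceEtp:
    def test_fao56_worked_example(self):
        """Standard daily worked case (Uccle, 6 July): Tmax 21.5, Tmin 12.3,
        ea 1.409 kPa, u2 2.078 m/s, Rs 22.07 MJ → ET0 = 3.88 mm/day."""
        es = (daily_vpd(21.5, 0.0) + daily_vpd(12.3, 0.0)) / 2.0
        rh_mean = 100.0 * 1.409 / es
        et0 = reference_etp(
            tmin=12.3,
            tmax=21.5,
            rh_pct=rh_mean,
            wind_2m=2.078,
            radiation_mj=22.07,
            latitude=50.8,
            doy=187,
            altitude_m=100.0,
        )
        assert et0 == pytest.approx(3.88, abs=0.12)

    def test_no_driving_gradient_is_near_zero(self):
        et0 = reference_etp(10.0, 10.0, 100.0, 0.0, 0.0, 45.0, 1, 0.0)
        assert et0 == pytest.approx(0.0, abs=0.05)

    def test_monotone_in_radiation(self):
        lo = reference_etp(12.0, 24.0, 60.0, 2.0, 10.0, 45.0, 180)
        hi = reference_etp(12.0, 24.0, 60.0, 2.0, 20.0, 45.0, 180)
        assert hi > lo


class TestScreen:
    def test_identity_feature_retained_with_unit_correlation(self):
        doys = np.array([100.0, 110.0, 120.0, 130.0])
        table = pd.DataFrame({"f_same": doys, "f_anti": -doys})
        retained, r = correlation_screen(table, doys)
        assert r["f_same"] == pytest.approx(1.0)
        assert r["f_anti"] == pytest.approx(-1.0)
        assert set(retained) == {"f_same", "f_anti"}

    def test_independent_noise_dropped(self, rng):
        doys = np.arange(100, 138).astype(float)
        noise = rng.standard_normal(38)
        # permutation sanity: noise uncorrelated with DOY at this n
        table = pd.DataFrame({"noise": noise})
        retained, r = correlation_screen(table, doys)
        assert abs(r["noise"]) < 0.3
        assert retained == []

    def test_zero_variance_feature_warned_and_dropped(self):
        doys = np.array([100.0, 101.0, 102.0])
        table = pd.DataFrame({"flat": np.ones(3)})
        with pytest.warns(UserWarning, match="zero variance"):
            retained, r = correlation_screen(table, doys)
        assert "flat" not in r.index


def toy_features(site_years, window, event_doys):
    rows = []
    for sy, event in zip(site_years, event_doys):
        for doy in range(window.doy_start - 5, window.doy_end + 6):
            rows.append({"site_year": sy, "doy": doy, "f": float(doy)})
    return pd.DataFrame(rows)


class TestAssembleBinary:
    def test_row_count_and_single_positive(self):
        window = STAGE_WINDOWS["budburst"]  # 65..100 → 36 days
        features = toy_features(["a"], window, [95])
        ds = assemble_binary(features, {"a": 95}, window)
        assert len(ds) == 36
        assert ds["label"].sum() == 1
        assert int(ds.loc[ds["label"] == 1, "doy"].iloc[0]) == 95

    def test_event_outside_window_excluded_with_warning(self):
        window = STAGE_WINDOWS["budburst"]
        features = toy_features(["a", "b"], window, [95, 120])
        with pytest.warns(UserWarning, match="outside"):
            ds = assemble_binary(features, {"a": 95, "b": 120}, window)
        assert set(ds["site_year"]) == {"a"}

    def test_two_site_years_two_positives(self):
        window = STAGE_WINDOWS["flowering"]
        features = toy_features(["a", "b"], window, [150, 160])
        ds = assemble_binary(features, {"a": 150, "b": 160}, window)
        assert ds["label"].sum() == 2


class TestRebalance:
    def _toy(self, n_pos=3, n_neg=30):
        return pd.DataFrame(
            {"x": np.arange(n_pos + n_neg, dtype=float), "label": [1] * n_pos + [0] * n_neg}
        )

    def test_oversample_to_parity(self):
        out = rebalance(self._toy(), "oversample", 1.0, seed=0)
        assert (out["label"] == 1).sum() == 30 and (out["label"] == 0).sum() == 30

    def test_undersample_to_parity(self):
        out = rebalance(self._toy(), "undersample", 1.0, seed=0)
        assert (out["label"] == 1).sum() == 3 and (out["label"] == 0).sum() == 3

    def test_deterministic_under_seed(self):
        a = rebalance(self._toy(), "oversample", 1.0, seed=5)
        b = rebalance(self._toy(), "oversample", 1.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rebalance(self._toy(n_pos=0), "oversample", 1.0, seed=0)


class TestSplit:
    def test_eighty_twenty_row_split(self):
        ds = pd.DataFrame({"x": np.arange(100.0), "label": 0})
        train, test = split_train_test(ds, 0.8, seed=1)
        assert len(train) == 80 and len(test) == 20
        merged = pd.concat([train, test])["x"].sort_values().to_numpy()
        assert (merged == np.arange(100.0)).all()

    def test_grouped_mode_holds_out_whole_units(self):
        rows = []
        for unit in range(22):
            for d in range(10):
                rows.append({"site_year": f"V{unit}", "doy": d, "label": 0})
        ds = pd.DataFrame(rows)
        train, test = split_train_test(ds, seed=3, group_col="site_year", n_test_groups=3)
        held = set(test["site_year"])
        assert len(held) == 3
        assert held.isdisjoint(set(train["site_year"]))
        assert len(train) + len(test) == len(ds)

    def test_reproducible(self):
        ds = pd.DataFrame({"x": np.arange(50.0), "label": 0})
        a1, b1 = split_train_test(ds, seed=9)
        a2, b2 = split_train_test(ds, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)


class TestLoocv:
    def _dataset(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 2))
        y = (x[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
        return pd.DataFrame({"f1": x[:, 0], "f2": x[:, 1], "label": y})

    def test_matches_explicit_exclusion_loop(self):
        ds = self._dataset()
        learner = LogisticRegression()
        scores, failures = loocv(ds, learner, ["f1", "f2"])
        assert failures == []
        for i in range(len(ds)):
            rest = ds.drop(index=i)
            m = LogisticRegression().fit(rest[["f1", "f2"]], rest["label"])
            expected = m.predict_proba(ds.loc[[i], ["f1", "f2"]])[0, list(m.classes_).index(1)]
            assert scores[i] == pytest.approx(expected, abs=1e-12)

    def test_constant_majority_learner(self):
        from sklearn.dummy import DummyClassifier

        ds = self._dataset()
        scores, failures = loocv(ds, DummyClassifier(strategy="most_frequent"), ["f1", "f2"])
        assert failures == []
        assert set(np.round(scores, 6)) <= {0.0, 1.0}

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            loocv(self._dataset(n=1), LogisticRegression(), ["f1", "f2"])


class TestEvaluate:
    def test_printed_formula_example(self):
        scores = np.concatenate([np.ones(8), np.ones(2), np.zeros(2), np.zeros(88)])
        labels = np.concatenate([np.ones(8), np.zeros(2), np.ones(2), np.zeros(88)])
        m = evaluate(scores, labels, 0.5)
        assert (m.tp, m.fp, m.fn, m.tn) == (8, 2, 2, 88)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.96)
        assert m.f1 == pytest.approx(0.8)

    def test_metrics_match_formulas_on_enumerated_matrices(self):
        for tp, fp, fn, tn in [(1, 0, 0, 9), (5, 5, 5, 5), (0, 3, 2, 10), (7, 1, 2, 40)]:
            scores = np.concatenate(
                [np.ones(tp), np.ones(fp), np.zeros(fn), np.zeros(tn)]
            )
            labels = np.concatenate(
                [np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
            )
            m = evaluate(scores, labels, 0.5)
            total = tp + fp + fn + tn
            assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert m.accuracy == pytest.approx((tp + tn) / total)
            denom = tp + 0.5 * (fp + fn)
            assert m.f1 == pytest.approx(tp / denom if denom else 0.0)

    def test_perfect_separation_auc(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert evaluate(scores, labels, 0.5).auc == 1.0

    def test_auc_equals_concordant_pair_fraction(self, rng):
        """AUC against the brute-force pairwise oracle with ties at ½,
        on 200 random 20-point score/label sets."""
        for _ in range(200):
            scores = np.round(rng.random(20), 1)  # coarse grid → ties occur
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            oracle = wins / (len(pos) * len(neg))
            assert evaluate(scores, labels, 0.5).auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_auc_missing(self):
        m = evaluate(np.array([0.1, 0.9]), np.array([0, 0]), 0.5)
        assert m.auc is None


class TestExtractEventDate:
    def _probs(self, mapping, window):
        doys = window.doys
        probs = np.zeros(len(doys))
        for d, p in mapping.items():
            probs[d - window.doy_start] = p
        return pd.DataFrame({"doy": doys, "probability": probs})

    def test_mean_of_candidate_days(self):
        window = STAGE_WINDOWS["budburst"]
        frame = self._probs({92: 0.9, 96: 0.8}, window)
        assert extract_event_date(frame, window, 0.5) == 94

    def test_single_candidate(self):
        window = STAGE_WINDOWS["flowering"]
        frame = self._probs({150: 0.7}, window)
        assert extract_event_date(frame, window, 0.5) == 150

    def test_no_reliable_prediction(self):
        window = STAGE_WINDOWS["flowering"]
        frame = self._probs({150: 0.4}, window)
        assert extract_event_date(frame, window, 0.5) is None

    def test_invalid_probability_rejected(self):
        window = STAGE_WINDOWS["flowering"]
        frame = self._probs({150: 0.4}, window)
        frame.loc[0, "probability"] = 1.4
        with pytest.raises(ValueError):
            extract_event_date(frame, window, 0.5)


class TestRmseDays:
    def test_examples(self):
        assert rmse_days([100], [102])[0] == pytest.approx(2.0)
        assert rmse_days([100, 104], [102, 104])[0] == pytest.approx(math.sqrt(2.0))
        assert rmse_days([100, 150], [100, 150])[0] == 0.0

    def test_no_prediction_excluded_and_counted(self):
        rmse, excluded = rmse_days([100, None, 104], [101, 150, 104])
        assert excluded == 1
        assert rmse == pytest.approx(math.sqrt(0.5))

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            rmse_days([None, None], [100, 101])


class TestBuildFeatures:
    def test_feature_table_shape_and_cumulants(self, weather_year):
        feats = build_features(weather_year, 45.1)
        assert len(feats) == len(weather_year)
        assert (np.diff(feats["cum_gdd"]) >= 0).all()
        assert (np.diff(feats["cum_radiation"]) > 0).all()
        assert (np.diff(feats["cum_etp"]) >= 0).all()
        assert feats["vpd_kpa"].min() >= 0

    def test_tsoil_fallback_is_lagged_smoothing(self, weather_year):
        without = weather_year.drop(columns=["tsoil"])
        feats = build_features(without, 45.1)
        assert feats["tsoil"].notna().all()
        # smoother than raw tmean
        assert feats["tsoil"].diff().abs().mean() < weather_year["tmean"].diff().abs().mean()


class TestClassifierFactory:
    @pytest.mark.parametrize("name", ["xgboost", "random_forest", "svm", "knn"])
    def test_benchmark_set_fits_and_scores(self, name, rng):
        x = rng.normal(size=(60, 3))
        y = (x[:, 0] > 0).astype(int)
        clf = make_classifier(name, seed=0)
        clf.fit(x, y)
        proba = clf.predict_proba(x)
        assert proba.shape == (60, 2)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("nonexistent")


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rebalance_bit_identical_under_seed(seed):
    ds = pd.DataFrame({"x": np.arange(40.0), "label": [1] * 4 + [0] * 36})
    a = rebalance(ds, "oversample", 1.0, seed=seed)
    b = rebalance(ds, "oversample", 1.0, seed=seed)
    assert sorted(a["x"]) == sorted(b["x"])
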