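"""Indicators, VEL calibration, bootstrap tuning and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from driftstate.classify import (
    CvResult,
    TuningGrid,
    VelModel,
    calibrate_vel,
    compare_methods,
    compute_indicators,
    confusion_counts,
    count_segments,
    cross_validate,
    optimize_threshold,
    predict_states,
    train_classifier,
    vel_classify,
)
from driftstate.features import FEATURE_COLUMNS


def naive_indicators(true, pred, track_ids):
    """Position-by-position recount oracle, independent of the implementation."""
    t, p, ids = list(true), list(pred), list(track_ids)
    ts = sum(1 for a, b in zip(t, p) if a == "S" and b == "S")
    tb = sum(1 for a, b in zip(t, p) if a == "B" and b == "B")
    fs = sum(1 for a, b in zip(t, p) if a == "B" and b == "S")
    fb = sum(1 for a, b in zip(t, p) if a == "S" and b == "B")
    n = len(t)

    def segs(seq):
        out = 0
        for tid in dict.fromkeys(ids):
            sub = [s for s, i in zip(seq, ids) if i == tid]
            out += 1 + sum(1 for a, b in zip(sub, sub[1:]) if a != b)
        return out

    return {
        "error_rate": (fb + fs) / n,
        "precision": ts / (ts + fs) if ts + fs else np.nan,
        "tsr": ts / (ts + fb) if ts + fb else np.nan,
        "fsr": fs / (fs + tb) if fs + tb else np.nan,
        "segmentation_rate": (segs(p) - segs(t)) / segs(t),
    }


class TestSegments:
    @pytest.mark.parametrize(
        "seq,expected", [("SSS", 1), ("BSB", 3), ("BSSBBS", 4), ("S", 1), ("BB", 1)]
    )
    def test_examples(self, seq, expected):
        assert count_segments(seq) == expected

    def test_exhaustive_run_enumeration(self):
        """Matches brute-force run enumeration for every sequence of length <= 10."""
        for n in range(1, 11):
            for seq in itertools.product("SB", repeat=n):
                brute = sum(1 for a, b in zip(seq, seq[1:]) if a != b) + 1
                assert count_segments(seq) == brute

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            count_segments("")


class TestIndicators:
    def test_perfect_prediction(self):
        ind = compute_indicators("BBSS", "BBSS")
        assert ind.error_rate == 0
        assert ind.precision == 1
        assert ind.tsr == 1
        assert ind.fsr == 0
        assert ind.segmentation_rate == 0

    def test_enumerated_example(self):
        # true BBSS vs pred BSSS: TS=2, FS=1, TB=1, FB=0
        c = confusion_counts("BBSS", "BSSS")
        assert (c.ts, c.fs, c.tb, c.fb) == (2, 1, 1, 0)
        ind = compute_indicators("BBSS", "BSSS")
        assert ind.error_rate == pytest.approx(0.25)
        assert ind.fsr == pytest.approx(0.5)
        assert ind.tsr == pytest.approx(1.0)

    def test_segmentation_rate_formula(self):
        # 4 observed segments, 6 predicted -> (6-4)/4 = 0.5
        true = "BBSSBBSS"
        pred = "BSBSBSBS"
        assert count_segments(true) == 4
        assert count_segments(pred) == 8
        ind = compute_indicators(true, pred)
        assert ind.segmentation_rate == pytest.approx(1.0)
        ind2 = compute_indicators("BSBS", "BSBSBS"[:4])
        assert ind2.segmentation_rate == 0.0

    def test_error_rate_complement_identity(self, rng):
        for _ in range(50):
            n = rng.integers(2, 40)
            t = rng.choice(["S", "B"], n)
            p = rng.choice(["S", "B"], n)
            c = confusion_counts(t, p)
            ind = compute_indicators(t, p)
            assert ind.error_rate == pytest.approx(1 - (c.ts + c.tb) / c.n)

    def test_fuzz_against_naive_recount(self, rng):
        """1,000 random (true, pred) pairs match the brute-force oracle."""
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            n_tracks = int(rng.integers(1, 4))
            t = rng.choice(["S", "B"], n)
            p = rng.choice(["S", "B"], n)
            ids = np.sort(rng.integers(0, n_tracks, n))
            got = compute_indicators(t, p, ids).as_dict()
            exp = naive_indicators(t, p, ids)
            for k in exp:
                if np.isnan(exp[k]):
                    assert np.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(exp[k]), k

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compute_indicators("SB", "S")

    def test_fsr_nan_without_observed_b(self):
        assert np.isnan(compute_indicators("SS", "SB").fsr)


class TestVel:
    def test_threshold_is_max_sea_speed(self):
        m = calibrate_vel([0.2, 0.9, 1.3, 5.0], ["S", "S", "S", "B"])
        assert m.threshold == 1.3

    def test_constant_speeds(self):
        assert calibrate_vel([0.7, 0.7], ["S", "S"]).threshold == 0.7

    def test_no_sea_positions_errors(self):
        with pytest.raises(ValueError):
            calibrate_vel([1.0], ["B"])

    def test_classification_rule_with_tie(self):
        m = VelModel(threshold=1.3)
        np.testing.assert_array_equal(
            vel_classify([0.5, 2.0, 1.3], m), ["S", "B", "S"]
        )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            VelModel(threshold=0.0)


def _separable_learning(rng, n_tracks=8, n_per=30):
    """Learning table with linearly separable speeds (S: 0-0.5, B: 3-7)."""
    rows = []
    for i in range(n_tracks):
        for j in range(n_per):
            state = "S" if j % 3 else "B"
            speed = rng.uniform(0, 0.5) if state == "S" else rng.uniform(3, 7)
            row = {c: rng.normal(0, 0.01) for c in FEATURE_COLUMNS}
            row.update(
                {
                    "buoy_id": f"t{i}",
                    "time": pd.Timestamp("2010-01-01") + pd.Timedelta(hours=j),
                    "state": state,
                    "speed": speed,
                    "speed_before": speed,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


class TestTraining:
    @pytest.mark.parametrize("method", ["mlr", "ann", "rf"])
    def test_separable_case_perfect(self, method, rng):
        df = _separable_learning(rng)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["state"].to_numpy()
        grid = TuningGrid(mlr_decay=(0.01,), ann_decay=(0.001,), ann_size=(8,),
                         rf_mtry=(3,), rf_trees=50, ann_max_iter=1000)
        est, _ = train_classifier(method, X[::2], y[::2], grid, seed=0)
        assert (predict_states(est, X[1::2]) == y[1::2]).mean() == 1.0

    def test_single_class_errors(self, rng):
        df = _separable_learning(rng)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        with pytest.raises(ValueError):
            train_classifier("rf", X, np.full(len(X), "S"), TuningGrid(), seed=0)

    def test_tuning_deterministic(self, rng):
        df = _separable_learning(rng, n_tracks=4, n_per=20)
        # add noise so tuning is non-trivial
        df["speed"] += rng.normal(0, 1.5, len(df))
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["state"].to_numpy()
        grid = TuningGrid(rf_mtry=(2, 4), n_boot=5, rf_trees=30)
        _, p1 = train_classifier("rf", X, y, grid, seed=7)
        _, p2 = train_classifier("rf", X, y, grid, seed=7)
        assert p1 == p2


class TestCrossValidation:
    def test_structure_and_split(self, rng):
        df = _separable_learning(rng)
        cv = cross_validate(
            df, methods=("vel", "mlr"), n_repeats=2, seed=3,
            grid=TuningGrid(mlr_decay=(0.1,)), keep_predictions=True,
        )
        assert len(cv.results) == 4  # 2 repeats x 2 methods
        all_ids = set(df["buoy_id"])
        for rep, (train_ids, valid_ids) in cv.splits.items():
            assert set(train_ids) | set(valid_ids) == all_ids
            assert set(train_ids) & set(valid_ids) == set()
            assert set(cv.predictions[rep]["buoy_id"]) == set(valid_ids)

    def test_vel_deterministic_given_split(self, rng):
        df = _separable_learning(rng)
        a = cross_validate(df, methods=("vel",), n_repeats=2, seed=9)
        b = cross_validate(df, methods=("vel",), n_repeats=2, seed=9)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_too_few_trajectories(self, rng):
        df = _separable_learning(rng, n_tracks=3)
        with pytest.raises(ValueError):
            cross_validate(df, methods=("vel",), n_repeats=1)


class TestComparison:
    def _cv_from(self, frames):
        return CvResult(results=pd.DataFrame(frames), n_repeats=3)

    def test_identical_method_ci_contains_zero(self, rng):
        rows = []
        for rep in range(5):
            e = rng.uniform(0.01, 0.1)
            for m in ("vel", "mlr"):
                rows.append(
                    {"repeat": rep, "method": m, "error_rate": e + rng.normal(0, 1e-4),
                     "precision": 0.9, "tsr": 0.99, "fsr": 0.2, "segmentation_rate": 0.5}
                )
        cmp_df = compare_methods(self._cv_from(rows))
        row = cmp_df.query("method == 'mlr' and indicator == 'error_rate'").iloc[0]
        assert row["ci_low"] <= 0 <= row["ci_high"]

    def test_constant_difference_degenerate_ci(self):
        rows = []
        for rep in range(4):
            base = 0.1 + 0.01 * rep
            rows.append({"repeat": rep, "method": "vel", "error_rate": base,
                         "precision": 1, "tsr": 1, "fsr": 0, "segmentation_rate": 0})
            rows.append({"repeat": rep, "method": "rf", "error_rate": base - 0.05,
                         "precision": 1, "tsr": 1, "fsr": 0, "segmentation_rate": 0})
        cmp_df = compare_methods(self._cv_from(rows))
        row = cmp_df.query("method == 'rf' and indicator == 'error_rate'").iloc[0]
        assert row["ci_low"] == pytest.approx(-0.05)
        assert row["ci_high"] == pytest.approx(-0.05)

    def test_ci_matches_bootstrap_oracle(self, rng):
        diffs = rng.normal(-0.03, 0.01, 40)
        rows = []
        for rep, d in enumerate(diffs):
            rows.append({"repeat": rep, "method": "vel", "error_rate": 0.1,
                         "precision": 1, "tsr": 1, "fsr": 0, "segmentation_rate": 0})
            rows.append({"repeat": rep, "method": "rf", "error_rate": 0.1 + d,
                         "precision": 1, "tsr": 1, "fsr": 0, "segmentation_rate": 0})
        cmp_df = compare_methods(self._cv_from(rows))
        row = cmp_df.query("method == 'rf' and indicator == 'error_rate'").iloc[0]
        boots = [rng.choice(diffs, diffs.size).mean() for _ in range(4000)]
        lo, hi = np.quantile(boots, [0.025, 0.975])
        assert row["ci_low"] == pytest.approx(lo, abs=0.002)
        assert row["ci_high"] == pytest.approx(hi, abs=0.002)


class TestThresholdOptimization:
    def test_separated_probabilities_gap_midpoint(self):
        p = [0.1, 0.2, 0.8, 0.9]
        y = ["B", "B", "S", "S"]
        t = optimize_threshold(p, y)
        assert 0.2 < t < 0.8

    def test_uninformative_probabilities(self, rng):
        p = rng.uniform(size=400)
        y = rng.choice(["S", "B"], 400)
        t = optimize_threshold(p, y)
        # exhaustive-scan oracle: no threshold can beat ~1 by much
        best = max(
            ((p >= c) & (y == "S")).sum() / (y == "S").sum()
            + ((p < c) & (y == "B")).sum() / (y == "B").sum()
            for c in np.linspace(0, 1, 201)
        )
        assert best <= 1.2
        assert 0.0 <= t <= 1.0

    def test_symmetric_calibrated_recovers_half(self, rng):
        p = np.concatenate([rng.uniform(0, 0.45, 200), rng.uniform(0.55, 1, 200)])
        y = np.array(["B"] * 200 + ["S"] * 200)
        assert optimize_threshold(p, y) == pytest.approx(0.5, abs=0.06)

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            optimize_threshold([0.1, 0.9], ["S", "S"])
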