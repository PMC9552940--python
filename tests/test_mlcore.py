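"""Cross-validation, random forest, agreement statistics, bootstrap, ablations."""

import numpy as np
import pandas as pd
import pytest

from pulseicp.features import FEATURE_NAMES, TABLE_COLUMNS
from pulseicp.mlcore import (
    RFConfig,
    balance_dataset,
    bland_altman,
    bootstrap_compare,
    cv_split,
    evaluate,
    feature_importance,
    run_cv,
    train_rf,
)


def _toy_table(n=200, n_subjects=2, seed=0, label_from="COMx"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f: rng.random(n) for f in FEATURE_NAMES})
    df["label_icp"] = 5 + 25 * df[label_from]
    df["subject_id"] = [f"S{i % n_subjects:02d}" for i in range(n)]
    df["trial_id"] = "t00"
    df["window_index"] = np.arange(n)
    df["modality"] = "dHbT"
    return df[TABLE_COLUMNS]


class TestCvSplit:
    def test_partition_contract(self):
        subj = np.array(["S00"] * 100)
        splits = cv_split(subj, k=5, seed=1)
        all_test = np.concatenate([t for _, t in splits])
        assert len(all_test) == 100 and len(np.unique(all_test)) == 100
        for train, test in splits:
            assert len(test) == 20
            assert not np.intersect1d(train, test).size
            assert len(train) + len(test) == 100

    def test_same_seed_identical(self):
        subj = np.array(["S00"] * 60 + ["S01"] * 60)
        a = cv_split(subj, seed=7)
        b = cv_split(subj, seed=7)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_every_subject_in_every_block(self):
        subj = np.array(["S00"] * 50 + ["S01"] * 50)
        for train, test in cv_split(subj, k=5, seed=3):
            assert set(subj[test]) == {"S00", "S01"}
            assert set(subj[train]) == {"S00", "S01"}


class TestTrainEvaluate:
    def test_constant_label_predicts_constant(self):
        rng = np.random.default_rng(0)
        x = rng.random((50, 8))
        with pytest.warns(UserWarning):
            model = train_rf(x, np.full(50, 9.0), RFConfig())
        np.testing.assert_allclose(model.predict(x), 9.0)

    def test_noiseless_single_feature_overfits(self):
        rng = np.random.default_rng(1)
        x = np.zeros((500, 8))
        x[:, 4] = rng.random(500)
        y = 3.0 * x[:, 4] + 1.0
        model = train_rf(x, y, RFConfig())
        r2, _, _ = evaluate(model, x, y)
        assert r2 >= 0.99

    def test_fixed_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((100, 8)), rng.random(100)
        p1 = train_rf(x, y, RFConfig(rng_seed=5)).predict(x)
        p2 = train_rf(x, y, RFConfig(rng_seed=5)).predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_perfect_predictions_score_one(self):
        class Identity:
            def predict(self, x):
                return x[:, 0]

        x = np.arange(10.0)[:, None]
        r2, mse, _ = evaluate(Identity(), x, x[:, 0])
        assert r2 == 1.0 and mse == 0.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])

        class Mean:
            def predict(self, x):
                return np.full(len(x), 2.5)

        r2, _, _ = evaluate(Mean(), np.zeros((4, 1)), y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_point_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.array([1.5, 2.0, 2.5, 4.0, 5.5])

        class Fixed:
            def predict(self, x):
                return pred

        r2, mse, _ = evaluate(Fixed(), np.zeros((5, 1)), y)
        # brute-force arithmetic: SSE = .25+0+.25+0+.25 = 0.75, MSE = 0.15,
        # var(y) = 2, r2 = 1 - 0.15/2 = 0.925
        assert mse == pytest.approx(0.15, abs=1e-12)
        assert r2 == pytest.approx(0.925, abs=1e-12)

    def test_r2_mse_variance_identity(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((80, 8)), rng.random(80) * 10
        model = train_rf(x[:60], y[:60], RFConfig())
        r2, mse, _ = evaluate(model, x[60:], y[60:])
        assert abs((1.0 - mse / np.var(y[60:])) - r2) <= 1e-9


class TestBlandAltman:
    def test_perfect_agreement(self):
        y = np.arange(10.0)
        assert bland_altman(y, y) == (0.0, 0.0, 0.0)

    def test_two_point_case(self):
        m, lo, hi = bland_altman(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert m == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_matches_arithmetic_oracle(self, rng):
        preds, labels = rng.random(100) * 30, rng.random(100) * 30
        m, lo, hi = bland_altman(preds, labels)
        d = [p - l for p, l in zip(preds, labels)]
        mean = sum(d) / len(d)
        sd = (sum((v - mean) ** 2 for v in d) / len(d)) ** 0.5
        assert abs(m - mean) <= 1e-12
        assert abs(lo - (mean - 1.96 * sd)) <= 1e-12
        assert abs(hi - (mean + 1.96 * sd)) <= 1e-12

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))


class TestFeatureImportance:
    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(4)
        x = rng.random((300, 8))
        y = 20 * x[:, 2] + 0.01 * rng.standard_normal(300)
        model = train_rf(x, y, RFConfig())
        frac, _, imp = feature_importance(model)
        assert np.argmax(frac) == 2
        assert np.argmax(imp) == 2

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = train_rf(rng.random((100, 8)), rng.random(100), RFConfig())
        frac, _, imp = feature_importance(model)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stump_forest_split_fraction_is_root_frequency(self):
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(6)
        x, y = rng.random((200, 8)), rng.random(200)
        model = RandomForestRegressor(
            n_estimators=50, max_depth=1, random_state=0, n_jobs=1
        ).fit(x, y)
        frac, _, _ = feature_importance(model)
        roots = np.bincount(
            [t.tree_.feature[0] for t in model.estimators_], minlength=8
        ) / len(model.estimators_)
        np.testing.assert_allclose(frac, roots, atol=1e-12)


class TestBootstrapCompare:
    def test_identical_sets_not_significant(self, rng):
        labels = rng.random(200) * 30
        preds = labels + rng.standard_normal(200)
        res = bootstrap_compare(preds, labels, preds, labels, n_boot=2000, seed=1)
        assert not res["significant"]
        assert abs(np.mean(res["r2_a"] - res["r2_b"])) < 0.05

    def test_constructed_separation_is_significant(self, rng):
        labels = rng.random(200) * 30
        good = labels.copy()
        bad = rng.permutation(labels)
        res = bootstrap_compare(good, labels, bad, labels, n_boot=2000, seed=2)
        assert res["significant"] and res["better"] == "a"

    def test_bootstrap_mean_tracks_full_sample_r2(self, rng):
        labels = rng.random(400) * 30
        preds = labels + rng.standard_normal(400)
        full_r2 = 1 - np.mean((preds - labels) ** 2) / np.var(labels)
        res = bootstrap_compare(preds, labels, preds, labels, n_boot=10000, seed=3)
        assert res["summary_a"]["mean"] == pytest.approx(full_r2, abs=0.02)


class TestAblateAndBalance:
    def test_ablation_drops_map_from_split_records(self):
        from pulseicp.mlcore import ablate_map

        table = _toy_table(n=200)
        rep = ablate_map(table, "dHbT", RFConfig(n_trees=20), seed=0)
        assert "MAP" not in rep.feature_names
        assert len(rep.split_fraction) == 7
        np.testing.assert_array_equal(rep.labels, table["label_icp"].to_numpy())

    def test_balance_identity_without_band_rows(self):
        table = _toy_table(n=100)
        table["label_icp"] = 20.0 + np.arange(100) * 0.05  # all above 10
        out = balance_dataset(table)
        assert len(out) == 100

    def test_balance_counting(self):
        table = _toy_table(n=150)
        table.loc[:99, "label_icp"] = 7.0   # 100 rows in [5, 10]
        table.loc[100:, "label_icp"] = 20.0  # 50 rows outside
        out = balance_dataset(table, seed=4)
        assert len(out) == 100
        assert (out["label_icp"] == 7.0).sum() == 50

    def test_balance_seed_deterministic(self):
        table = _toy_table(n=100)
        table["label_icp"] = 7.0
        a = balance_dataset(table, seed=9)
        b = balance_dataset(table, seed=9)
        assert a.equals(b)


def test_run_cv_report_is_consistent():
    table = _toy_table(n=250, seed=8)
    rep = run_cv(table, "dHbT", RFConfig(n_trees=30), seed=0)
    assert len(rep.fold_r2) == 5
    assert np.isfinite(rep.predictions).all()
    # pooled Bland-Altman mean equals mean(ICPest - ICPinv) exactly
    assert rep.ba_mean == pytest.approx(float(np.mean(rep.predictions - rep.labels)), abs=1e-12)
    # per-fold r2/MSE identity against pooled label variance is not expected,
    # but each fold's values must satisfy r2 <= 1 and MSE >= 0
    assert all(r <= 1.0 for r in rep.fold_r2)
    assert all(m >= 0.0 for m in rep.fold_mse)
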