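"""Label encoding, classifier training, metrics, leave-one-file-out CV."""

import math

import numpy as np
import pandas as pd
import pytest

from vesisort.phantom import sample_feature_table
from vesisort.train_eval import (ConfusionCounts, TrainingConfig,
                                 compute_metrics, confusion_counts,
                                 encode_labels, leave_one_file_out_cv, train)


def _table(labels, seed=0):
    rng = np.random.default_rng(seed)
    n = len(labels)
    return pd.DataFrame({
        "r": rng.normal(10, 2, n), "gv": rng.normal(128, 4, n),
        "GVSD": rng.normal(6, 1, n), "distAZ": rng.normal(250, 100, n),
        "label": labels,
    })


class TestEncodeLabels:
    def test_published_code_mapping(self):
        ds = encode_labels([_table(["C", "D", "N", "E", "D"])])
        # D -> -1, E removed, C and N -> +1
        assert list(ds.y) == [1, -1, 1, -1]
        assert len(ds.X) == 4

    def test_unknown_code_reports_row(self):
        with pytest.raises(ValueError, match="row 1"):
            encode_labels([_table(["C", "Q"])])

    def test_group_ids_follow_sources(self):
        ds = encode_labels([_table(["C"] * 3), _table(["D"] * 2)],
                           sources=["a", "b"])
        assert list(ds.groups) == ["a", "a", "a", "b", "b"]


class TestTrain:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X = pd.DataFrame({"r": [8, 9, 15, 16], "gv": [120, 121, 140, 141],
                          "GVSD": [7, 7, 4, 4], "distAZ": [100, 90, 400, 410]})
        df = X.assign(label=["C", "C", "D", "D"])
        model = train(encode_labels([df]), TrainingConfig())
        assert (model.predict(X) == [1, 1, -1, -1]).all()

    def test_single_class_svm_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            train(encode_labels([_table(["C", "C", "C"])]), TrainingConfig())

    def test_exported_linear_model_matches_trainer_predictions(self):
        table = sample_feature_table(n=600, dcv_fraction=0.25, seed=21)
        ds = encode_labels([table])
        model = train(ds, TrainingConfig())
        exported = model.to_linear_model()
        from vesisort.classifier import classify_table
        out, _ = classify_table(ds.X, exported)
        via_classifier = np.where(out["class"] == "CCV", 1, -1)
        assert (via_classifier == model.predict(ds.X)).all()

    @pytest.mark.parametrize("algo", ["random_forest", "knn", "svm_rbf"])
    def test_alternative_classifiers_fit_and_predict(self, algo):
        table = sample_feature_table(n=300, dcv_fraction=0.3, seed=4)
        ds = encode_labels([table])
        cfg = TrainingConfig(algorithm=algo, seed=11)
        p1 = train(ds, cfg).predict(ds.X)
        p2 = train(ds, cfg).predict(ds.X)
        assert (p1 == p2).all()            # seeded determinism
        assert set(np.unique(p1)) <= {-1, 1}

    def test_rf_export_refused(self):
        ds = encode_labels([sample_feature_table(n=100, dcv_fraction=0.3, seed=2)])
        model = train(ds, TrainingConfig(algorithm="random_forest"))
        with pytest.raises(ValueError):
            model.to_linear_model()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainingConfig(algorithm="perceptron")
        with pytest.raises(ValueError):
            TrainingConfig(C=-1.0)


class TestMetrics:
    def test_closed_form_example(self):
        m = compute_metrics(ConfusionCounts(tp=9, fp=1, fn=1, tn=89))
        assert m["precision_DCV"] == pytest.approx(0.9)
        assert m["recall_DCV"] == pytest.approx(0.9)
        assert m["F_DCV"] == pytest.approx(0.9)
        assert m["accuracy"] == pytest.approx(0.98)

    def test_f_is_harmonic_mean(self):
        m = compute_metrics(ConfusionCounts(tp=1, fp=0, fn=1, tn=0))
        assert m["precision_DCV"] == 1.0 and m["recall_DCV"] == 0.5
        assert m["F_DCV"] == pytest.approx(2 / 3)

    def test_degenerate_counts_undefined_but_accurate(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert math.isnan(m["precision_DCV"])
        assert math.isnan(m["recall_DCV"])
        assert math.isnan(m["F_DCV"])
        assert m["accuracy"] == 1.0

    def test_matches_brute_force_confusion_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            y_true = rng.choice([-1, 1], size=50)
            y_pred = rng.choice([-1, 1], size=50)
            c = confusion_counts(y_true, y_pred)
            # oracle: explicit per-row comparison
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == -1 and p == -1)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == -1)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == -1 and p == 1)
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert c.total == 50
            m = compute_metrics(c)
            if tp + fp:
                assert m["precision_DCV"] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m["recall_DCV"] == pytest.approx(tp / (tp + fn))

    def test_f_between_precision_and_recall(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            c = ConfusionCounts(*rng.integers(1, 30, size=4))
            m = compute_metrics(c)
            assert min(m["precision_DCV"], m["recall_DCV"]) - 1e-12 \
                <= m["F_DCV"] <= max(m["precision_DCV"], m["recall_DCV"]) + 1e-12


class TestLeaveOneFileOut:
    def test_one_fold_per_file(self):
        tables = [sample_feature_table(n=80, dcv_fraction=0.2, seed=s,
                                       source=f"t{s}") for s in range(15)]
        report = leave_one_file_out_cv(tables)
        assert report.n_folds == 15
        assert sorted(f["source"] for f in report.folds) == \
            sorted(f"t{s}" for s in range(15))

    def test_every_row_validated_exactly_once(self):
        tables = [sample_feature_table(n=60, dcv_fraction=0.2, seed=s,
                                       source=f"t{s}") for s in range(4)]
        report = leave_one_file_out_cv(tables)
        assert sum(f["counts"].total for f in report.folds) == 240

    def test_identical_separable_files_give_zero_sd(self):
        base = pd.DataFrame({
            "r": [8.0, 8.5, 16.0, 16.5] * 5, "gv": [120.0, 121, 140, 141] * 5,
            "GVSD": [7.0, 7, 4, 4] * 5, "distAZ": [100.0, 90, 400, 410] * 5,
            "label": ["C", "C", "D", "D"] * 5,
        })
        report = leave_one_file_out_cv([base.copy(), base.copy()],
                                       sources=["a", "b"])
        summ = report.summary()
        assert summ["F_DCV"] == (1.0, 0.0)
        assert summ["accuracy"] == (1.0, 0.0)

    def test_standardization_ignores_held_out_rows(self):
        tables = [sample_feature_table(n=60, dcv_fraction=0.3, seed=s,
                                       source=f"t{s}") for s in range(3)]
        report = leave_one_file_out_cv(tables)
        # corrupt the held-out file of fold 0 wildly; training mu/sigma of
        # that fold must not move
        corrupted = [t.copy() for t in tables]
        corrupted[0][["r", "gv", "GVSD", "distAZ"]] *= 100.0
        report2 = leave_one_file_out_cv(corrupted, sources=["t0", "t1", "t2"])
        f0 = next(f for f in report.folds if f["source"] == "t0")
        g0 = next(f for f in report2.folds if f["source"] == "t0")
        np.testing.assert_allclose(f0["mu"], g0["mu"])
        np.testing.assert_allclose(f0["sigma"], g0["sigma"])

    def test_fewer_than_two_files_rejected(self):
        with pytest.raises(ValueError, match="2"):
            leave_one_file_out_cv([_table(["C", "D"])])

    def test_undefined_fold_metrics_excluded_from_summary(self):
        # one validation file without any DCV: its precision/recall are
        # undefined and must not drag the averages
        ccv_only = _table(["C"] * 30, seed=1)
        mixed = [sample_feature_table(n=80, dcv_fraction=0.3, seed=s,
                                      source=f"m{s}") for s in range(2)]
        report = leave_one_file_out_cv(mixed + [ccv_only],
                                       sources=["m0", "m1", "ccv"])
        fold = next(f for f in report.folds if f["source"] == "ccv")
        assert math.isnan(fold["metrics"]["recall_DCV"])
        mean_f, _ = report.summary()["F_DCV"]
        assert not math.isnan(mean_f)
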