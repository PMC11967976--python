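"""Chi-square selection, classifiers, metrics, and validation strategies."""

import numpy as np
import pandas as pd
import pytest

from endeeg.errors import ValidationError
from endeeg.features import channel_feature_table
from endeeg.select_eval import (
    ChiSquareConfig,
    ClassifierSpec,
    SplitConfig,
    chi_square_scores,
    concat_channel_features,
    confusion_counts,
    evaluate,
    fit_predict,
    metrics,
    select_features,
)
from endeeg.synthetic import SyntheticSpec, generate_cohort


def _tab(subjects, n_feats, prefix="f", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        for i in range(2):
            row = {"subject_id": s, "label": "adhd", "segment_index": i}
            row.update({f"{prefix}{j}": rng.random() for j in range(n_feats)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestConcatChannelFeatures:
    def test_three_slbp_channels_give_93_columns(self, small_cohort):
        tabs = [(ch, channel_feature_table(small_cohort[:4], ch, "slbp"))
                for ch in ("Fz", "Cz", "Pz")]
        fm = concat_channel_features(tabs)
        assert fm.shape[1] - 3 == 93
        assert fm.columns[3].startswith("Fz:")

    def test_single_channel_is_rename_only(self):
        t = _tab(["a"], 4)
        fm = concat_channel_features([("Cz", t)])
        assert list(fm.columns[3:]) == [f"Cz:f{j}" for j in range(4)]
        np.testing.assert_array_equal(fm.iloc[:, 3:].to_numpy(), t.iloc[:, 3:].to_numpy())

    def test_misaligned_rows_rejected(self):
        with pytest.raises(ValidationError, match="not aligned"):
            concat_channel_features([("A", _tab(["a", "b"], 2)), ("B", _tab(["a"], 2))])


class TestChiSquare:
    def test_perfect_association_scores_20(self):
        f = pd.DataFrame({"f": [0.0] * 10 + [1.0] * 10})
        y = np.array(["adhd"] * 10 + ["control"] * 10)
        score = chi_square_scores(f, y, ChiSquareConfig(n_feature_bins=2))["f"]
        assert score == pytest.approx(20.0, abs=1e-12)

    def test_constant_feature_scores_zero(self):
        f = pd.DataFrame({"f": [2.0] * 20})
        y = np.array(["adhd"] * 10 + ["control"] * 10)
        assert chi_square_scores(f, y)["f"] == 0.0

    def test_matches_contingency_oracle_on_random_matrices(self):
        """Equality with an explicit scipy contingency-table evaluation."""
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(17)
        cfg = ChiSquareConfig(n_feature_bins=5)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            v = rng.normal(size=n)
            y = rng.choice(["adhd", "control"], size=n)
            if len(np.unique(y)) < 2:
                continue
            score = chi_square_scores(pd.DataFrame({"f": v}), y, cfg)["f"]
            edges = np.linspace(v.min(), v.max(), 6)
            idx = np.clip(np.digitize(v, edges[1:-1]), 0, 4)
            table = pd.crosstab(idx, y).to_numpy()
            expected = chi2_contingency(table, correction=False).statistic
            assert score == pytest.approx(expected, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_scores(pd.DataFrame({"f": [1.0, 2.0]}), np.array(["a", "a"]))


class TestSelectFeatures:
    def _f(self, n=4):
        return pd.DataFrame({f"f{i}": np.arange(3.0) for i in range(n)})

    def test_top_k_keeps_original_order(self):
        scores = pd.Series({"f0": 5.0, "f1": 0.0, "f2": 9.0})
        kept = select_features(self._f(3), scores, ChiSquareConfig(selection_rule="top-k", k=2))
        assert list(kept.columns) == ["f0", "f2"]

    def test_top_k_identity(self):
        f = self._f(3)
        scores = pd.Series({"f0": 1.0, "f1": 2.0, "f2": 3.0})
        kept = select_features(f, scores, ChiSquareConfig(selection_rule="top-k", k=3))
        assert list(kept.columns) == list(f.columns)

    def test_above_median(self):
        scores = pd.Series({"f0": 1.0, "f1": 2.0, "f2": 3.0, "f3": 4.0})
        kept = select_features(self._f(4), scores, ChiSquareConfig())
        assert list(kept.columns) == ["f2", "f3"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_features(self._f(3), pd.Series({"f0": 1.0, "f1": 1.0, "f2": 1.0}),
                            ChiSquareConfig(selection_rule="top-k", k=4))


class TestFitPredict:
    def test_knn_identity_point(self):
        train = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]})
        labels = ["control", "adhd"]
        pred = fit_predict(ClassifierSpec("knn"), train, labels, train.iloc[[1]])
        assert pred[0] == "adhd"

    @pytest.mark.parametrize("kind", ["knn", "svm-rbf", "ensemble"])
    def test_separable_blobs_are_perfect(self, kind):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.1, size=(20, 2))
        b = rng.normal([5, 5], 0.1, size=(20, 2))
        train = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        labels = ["control"] * 20 + ["adhd"] * 20
        test = pd.DataFrame(np.vstack([a + 0.05, b + 0.05]), columns=["x", "y"])
        pred = fit_predict(ClassifierSpec(kind), train, labels, test, seed=1)
        assert list(pred) == labels

    def test_single_class_training_rejected(self):
        train = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            fit_predict(ClassifierSpec("knn"), train, ["adhd", "adhd"], train)


class TestMetrics:
    def test_hand_values(self):
        assert metrics(9, 1, 8, 2) == (85.0, 90.0, 80.0)

    def test_perfect_and_worst(self):
        assert metrics(10, 0, 10, 0) == (100.0, 100.0, 100.0)
        assert metrics(0, 10, 0, 10) == (0.0, 0.0, 0.0)

    def test_undefined_component_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            acc, sens, spec = metrics(0, 0, 5, 5)
        assert np.isnan(sens) and acc == 50.0 and spec == 50.0

    def test_accuracy_between_prevalence_weighted_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fn, tn, fp = rng.integers(1, 30, size=4)
            acc, sens, spec = metrics(tp, fn, tn, fp)
            w = (tp + fn) / (tp + fn + tn + fp)
            assert acc == pytest.approx(w * sens + (1 - w) * spec, abs=1e-9)

    def test_confusion_counts(self):
        y = ["adhd", "adhd", "control", "control"]
        p = ["adhd", "control", "control", "adhd"]
        assert confusion_counts(y, p) == (1, 1, 1, 1)


@pytest.fixture(scope="module")
def eval_cohort():
    # bimodal effect: visible to SLBP (waveform shape), not just variance
    return generate_cohort(
        SyntheticSpec(n_per_class=10, n_channels=5, duration=32.0,
                      informative_channels=frozenset({0, 1}),
                      effect_kind="bimodal-mixture", effect_size=4.0, seed=21)
    )


class TestEvaluate:
    def test_kfold_partitions_units(self, eval_cohort):
        report = evaluate(eval_cohort, extractor="slbp",
                          split=SplitConfig(strategy="kfold-10", seed=0))
        total_test_segments = sum(f["n_test_segments"] for f in report.folds)
        # 20 subjects x 5 ch -> but features only for top-3; 2 segments per
        # subject per channel: each subject tested exactly once
        assert total_test_segments == 20 * 2
        assert sum(report.confusion.values()) == 20 * 2

    def test_random_split_deterministic(self, eval_cohort):
        kw = dict(extractor="slbp", split=SplitConfig(strategy="random-70-30-x10", seed=5))
        r1 = evaluate(eval_cohort, **kw)
        r2 = evaluate(eval_cohort, **kw)
        assert r1.to_dict() == r2.to_dict()

    def test_bimodal_effect_classified_above_chance(self, eval_cohort):
        report = evaluate(eval_cohort, criterion="end", extractor="slbp",
                          classifier=ClassifierSpec("knn"))
        assert report.accuracy >= 80.0

    def test_segment_granularity_chrono(self, eval_cohort):
        report = evaluate(eval_cohort, extractor="slbp",
                          split=SplitConfig(granularity="segment"))
        # 2 windows per subject: 1 train + 1 test each
        assert report.folds[0]["n_train_segments"] == 20
        assert report.folds[0]["n_test_segments"] == 20

    def test_leakage_guard_test_rows_do_not_affect_fitted_state(self, eval_cohort):
        """Perturbing the held-out recordings must leave the training-derived
        channel ranking and retained feature set unchanged."""
        base = evaluate(eval_cohort, extractor="slbp")
        cut = int(len(eval_cohort) * 0.7)
        perturbed = list(eval_cohort[:cut])
        rng = np.random.default_rng(99)
        for rec in eval_cohort[cut:]:
            perturbed.append(
                type(rec)(rec.subject_id, rec.label, rec.fs, list(rec.channel_names),
                          rng.normal(size=rec.data.shape) * 50)
            )
        alt = evaluate(perturbed, extractor="slbp")
        assert alt.folds[0]["channels"] == base.folds[0]["channels"]
        assert alt.folds[0]["n_features"] == base.folds[0]["n_features"]

    def test_top_n_out_of_range_rejected(self, eval_cohort):
        with pytest.raises(ValidationError, match="top_n"):
            evaluate(eval_cohort, top_n=25)

    def test_too_few_units_for_kfold_rejected(self):
        recs = generate_cohort(SyntheticSpec(n_per_class=3, n_channels=3, duration=16.0,
                                             informative_channels=frozenset({0}), seed=0))
        with pytest.raises(ValidationError, match="fewer"):
            evaluate(recs, extractor="slbp", split=SplitConfig(strategy="kfold-10"))
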