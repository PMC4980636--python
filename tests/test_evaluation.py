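import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from m1apred._errors import CompatibilityError, EvaluationError, ParameterError
from m1apred.classifier import SVMConfig
from m1apred.evaluation import (
    ABLATION_MASKS,
    ConfusionCounts,
    EvalReport,
    UndefinedMCCWarning,
    ablation_study,
    compute_metrics,
    cross_evaluate,
    cross_matrix,
    jackknife_evaluate,
    kfold_evaluate,
    roc_pr_curves,
)
from m1apred.synthetic_data import SyntheticSpec, generate_dataset, generate_two_domains


def mcc_by_formula(tp, tn, fp, fn):
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return (float(tp) * tn - float(fp) * fn) / denom if denom else math.nan


class TestComputeMetrics:
    def test_perfect_classifier(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(50, 50, 0, 0))
        assert (sn, sp, acc, mcc) == (100.0, 100.0, 100.0, 1.0)

    def test_perfect_anticlassifier(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(0, 0, 50, 50))
        assert (sn, sp, acc, mcc) == (0.0, 0.0, 0.0, -1.0)

    def test_mixed_counts_match_direct_substitution(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(TP=25, FN=25, TN=40, FP=10))
        assert sn == pytest.approx(50.0)
        assert sp == pytest.approx(80.0)
        assert acc == pytest.approx(65.0)
        assert mcc == pytest.approx(mcc_by_formula(25, 40, 10, 25))

    def test_undefined_mcc_is_nan_with_warning(self):
        with pytest.warns(UndefinedMCCWarning):
            _, _, _, mcc = compute_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=5))
        assert math.isnan(mcc)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(-1, 0, 0, 1)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_identities_on_random_tables(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMCCWarning)
            sn, sp, acc, mcc = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        if tp + fn:
            assert sn == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert sp == pytest.approx(100 * tn / (tn + fp))
        assert acc == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))
        if not math.isnan(mcc):
            assert -1.0 <= mcc <= 1.0
            assert mcc == pytest.approx(mcc_by_formula(tp, tn, fp, fn))


class TestRocPr:
    def test_perfect_separation(self):
        roc, pr, auroc, auprc = roc_pr_curves([3.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
        assert auroc == 1.0
        assert auprc == 1.0

    def test_four_score_worked_example(self):
        # pairs: (0.9 vs 0.6) ok, (0.9 vs 0.1) ok, (0.4 vs 0.6) bad,
        # (0.4 vs 0.1) ok -> 3/4
        _, _, auroc, _ = roc_pr_curves([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert auroc == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        _, _, auroc, _ = roc_pr_curves(scores, labels)
        assert abs(auroc - 0.5) < 0.05

    def test_roc_endpoints(self):
        roc, _, _, _ = roc_pr_curves([0.2, 0.8, 0.5, 0.4], [0, 1, 1, 0])
        assert roc[0].tolist() == [0.0, 0.0]
        assert roc[-1].tolist() == [1.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_pr_curves([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 10_000))
    def test_auroc_equals_normalized_mann_whitney_u(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n_pos + n_neg), 2)  # force ties
        labels = np.array([1] * n_pos + [0] * n_neg)
        _, _, auroc, _ = roc_pr_curves(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auroc == pytest.approx(u / (n_pos * n_neg), abs=1e-9)


class TestProtocols:
    def test_jackknife_separable_data_is_perfect(self):
        # a wide deterministic signal makes the classes truly separable even
        # for leave-one-out at small n (a narrow signal at tiny n triggers
        # the well-known LOO majority-flip artifact instead)
        signal = tuple(
            (off, (0.0, 0.0, 1.0, 0.0))
            for off in list(range(-8, 0)) + list(range(1, 9))
        )
        ds = generate_dataset(
            SyntheticSpec(n_pos=12, n_neg=12, seed=21, signal_positions=signal)
        )
        config = SVMConfig(
            C_grid=(1.0, 8.0, 64.0),
            gamma_grid=(2.0**-5, 2.0**-3, 2.0**-1),
            inner_cv_folds=3,
            seed=7,
        )
        report = jackknife_evaluate(ds, config)
        assert report.Acc == 100.0
        assert report.counts.total == len(ds)
        assert report.scheme == "jackknife"

    def test_jackknife_needs_two_per_class(self, small_svm_config):
        ds = generate_dataset(SyntheticSpec(n_pos=1, n_neg=5, seed=1))
        with pytest.raises(EvaluationError):
            jackknife_evaluate(ds, small_svm_config)

    def test_kfold_separable_and_deterministic(
        self, strong_signal_dataset, small_svm_config
    ):
        rep1 = kfold_evaluate(strong_signal_dataset, k=5, config=small_svm_config, seed=3)
        rep2 = kfold_evaluate(strong_signal_dataset, k=5, config=small_svm_config, seed=3)
        assert rep1.Acc >= 95.0
        assert np.array_equal(rep1.scores, rep2.scores)
        assert np.array_equal(rep1.fold_assignment, rep2.fold_assignment)
        assert rep1.summary() == rep2.summary()

    def test_kfold_partitions_dataset_exactly_once(
        self, strong_signal_dataset, small_svm_config
    ):
        rep = kfold_evaluate(strong_signal_dataset, k=5, config=small_svm_config, seed=3)
        assert rep.counts.total == len(strong_signal_dataset)
        assert sorted(np.unique(rep.fold_assignment)) == list(range(5))
        # every fold is non-empty and all records got exactly one score
        assert len(rep.scores) == len(strong_signal_dataset)

    def test_kfold_small_class_rejected(self, small_svm_config):
        ds = generate_dataset(SyntheticSpec(n_pos=4, n_neg=40, seed=2))
        with pytest.raises(EvaluationError):
            kfold_evaluate(ds, k=10, config=small_svm_config)

    def test_null_data_scores_near_chance(self, null_dataset, small_svm_config):
        rep = kfold_evaluate(null_dataset, k=5, config=small_svm_config, seed=4)
        # n=120: 3 binomial SE around 50% is ~13.7 points
        assert abs(rep.Acc - 50.0) < 20.0
        assert abs(rep.AUROC - 0.5) < 0.2

    def test_cross_self_equals_resubstitution(self, strong_signal_dataset, small_svm_config):
        from m1apred.classifier import grid_search_train, predict

        model = grid_search_train(strong_signal_dataset, small_svm_config)
        with pytest.warns(UserWarning, match="shared"):
            rep = cross_evaluate(
                strong_signal_dataset, strong_signal_dataset, model=model
            )
        preds = predict(model, strong_signal_dataset.records)
        resub = (
            (preds["call"] == "positive").astype(int)
            == np.asarray(strong_signal_dataset.labels())
        ).mean()
        assert rep.Acc == pytest.approx(100 * resub)

    def test_cross_window_length_mismatch_rejected(self, small_svm_config):
        a = generate_dataset(SyntheticSpec(n_pos=5, n_neg=5, seed=1))
        b = generate_dataset(SyntheticSpec(n_pos=5, n_neg=5, window_length=21, seed=1))
        with pytest.raises(CompatibilityError):
            cross_evaluate(a, b, small_svm_config)

    def test_cross_matrix_has_tag_axes(self, small_svm_config):
        a, b = generate_two_domains(
            SyntheticSpec(n_pos=20, n_neg=20, seed=5, tag="A"),
            SyntheticSpec(n_pos=20, n_neg=20, seed=6, tag="B"),
            shared=True,
        )
        matrix = cross_matrix([a, b], small_svm_config)
        assert list(matrix.index) == ["A", "B"]
        assert list(matrix.columns) == ["A", "B"]
        assert (matrix.to_numpy() >= 0).all() and (matrix.to_numpy() <= 100).all()


class TestAblation:
    def test_five_masks_reported(self, strong_signal_dataset, small_svm_config):
        table = ablation_study(strong_signal_dataset, small_svm_config, k=3, seed=1)
        assert len(table) == 5
        assert set(table["mask"]) == set(ABLATION_MASKS)

    def test_combined_mask_not_worse_than_best_single_channel(
        self, strong_signal_dataset, small_svm_config
    ):
        table = ablation_study(strong_signal_dataset, small_svm_config, k=3, seed=1)
        single = table[table["mask"] != "all"]["Acc_percent"].max()
        combined = table[table["mask"] == "all"]["Acc_percent"].iloc[0]
        assert combined >= single - 5.0  # allow fold noise


class TestEvalReport:
    def test_metrics_recomputable_from_counts(self, strong_signal_dataset, small_svm_config):
        rep = kfold_evaluate(strong_signal_dataset, k=5, config=small_svm_config, seed=3)
        sn, sp, acc, mcc = compute_metrics(rep.counts)
        assert (rep.Sn, rep.Sp, rep.Acc) == (sn, sp, acc)
        assert rep.MCC == pytest.approx(mcc, nan_ok=True)

    def test_json_round_trip_carries_provenance(self, tmp_path, strong_signal_dataset, small_svm_config):
        import json

        rep = kfold_evaluate(strong_signal_dataset, k=5, config=small_svm_config, seed=3)
        path = tmp_path / "report.json"
        rep.to_json(path)
        data = json.loads(path.read_text())
        assert data["scheme"] == "kfold(5)"
        assert data["seed"] == 3
        assert data["TP"] + data["TN"] + data["FP"] + data["FN"] == len(
            strong_signal_dataset
        )
        assert data["roc_points"][0] == [0.0, 0.0]
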