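"""Protocol checks: stratified splitting, losses, fusion, voting, metrics
against a brute-force oracle, and the training-loop contracts."""

import numpy as np
import pytest

from moafuse.datamodel import CompoundRecord, ConfigurationError
from moafuse.fp_cs import FPBranchConfig
from moafuse.mresnet import BackboneConfig
from moafuse.train_eval import (
    TrainConfig,
    compound_vote,
    compute_metrics,
    cross_entropy,
    fuse_scores,
    run_protocol,
    stratified_split,
    train_branch,
)

SMALL_FP = FPBranchConfig(d=32, d_c=32, d_s=32, d_f=16, fpc_hidden=64, fps_hidden=32,
                          fusion_hidden=32)


def recs(labels):
    return [CompoundRecord(f"c{i:03d}", "", y) for i, y in enumerate(labels)]


class TestStratifiedSplit:
    def test_balanced_classes_divide_exactly(self):
        plan = stratified_split(recs([0] * 10 + [1] * 10), k=10, seed=0)
        per_subset = {}
        for cid, s in plan.assignment.items():
            per_subset.setdefault(s, []).append(cid)
        assert all(len(v) == 2 for v in per_subset.values())

    def test_round_robin_counts_differ_by_at_most_one(self):
        plan = stratified_split(recs([0] * 23), k=10, seed=1)
        counts = np.bincount(list(plan.assignment.values()), minlength=10)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 23

    def test_same_seed_reproduces_assignment(self):
        r = recs([0] * 7 + [1] * 9 + [2] * 5)
        a = stratified_split(r, k=10, seed=42)
        b = stratified_split(r, k=10, seed=42)
        assert a.assignment == b.assignment

    def test_subsets_partition_compounds(self):
        r = recs([0] * 13 + [1] * 8)
        plan = stratified_split(r, k=10, seed=0)
        assert set(plan.assignment) == {c.compound_id for c in r}
        assert set(plan.assignment.values()) <= set(range(10))

    def test_folds_have_eight_train_one_val_and_never_the_test_subset(self):
        plan = stratified_split(recs([0] * 30), k=10, seed=0)
        assert len(plan.folds) == 5
        for train, val in plan.folds:
            assert len(train) == 8
            assert val not in train
            assert plan.test_subset not in train and plan.test_subset != val

    def test_k_of_one_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(recs([0, 1]), k=1)


class TestCrossEntropy:
    def test_uniform_ten_class_scores(self):
        assert cross_entropy(np.full(10, 0.1), 3) == pytest.approx(2.302585, abs=1e-6)

    def test_perfect_prediction_is_zero(self):
        s = np.zeros(4)
        s[2] = 1.0
        assert cross_entropy(s, 2) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert cross_entropy(np.array([0.7, 0.2, 0.1]), 0) == pytest.approx(0.356675, abs=1e-6)

    def test_zero_probability_is_clamped_not_infinite(self):
        s = np.array([0.0, 1.0])
        assert np.isfinite(cross_entropy(s, 0))


class TestFusion:
    def test_endpoints_return_branch_scores_bitwise(self, rng):
        a, b = rng.random((5, 3)), rng.random((5, 3))
        assert np.array_equal(fuse_scores(a, b, 1.0), a)
        assert np.array_equal(fuse_scores(a, b, 0.0), b)

    def test_half_mix_of_pure_vectors(self):
        out = fuse_scores(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.5)
        assert np.allclose(out, [0.5, 0.5])

    def test_convex_combination_stays_a_probability_vector(self, rng):
        a = rng.dirichlet(np.ones(4), size=6)
        b = rng.dirichlet(np.ones(4), size=6)
        for beta in (0.0, 0.3, 0.7, 1.0):
            out = fuse_scores(a, b, beta)
            assert np.all(out >= 0)
            assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            fuse_scores(np.ones(2), np.ones(2), 1.5)


class TestCompoundVote:
    def test_majority_wins(self):
        preds = [("A", [0.9, 0.1]), ("A", [0.8, 0.2]), ("A", [0.1, 0.9])]
        assert compound_vote(preds)["A"] == 0

    def test_single_sample_uses_its_argmax(self):
        assert compound_vote([("B", [0.2, 0.8])])["B"] == 1

    def test_tie_broken_by_highest_mean_score(self):
        preds = [("C", [0.60, 0.40]), ("C", [0.20, 0.70])]  # one vote each
        # mean scores: class0 0.40, class1 0.55 -> class 1 wins
        assert compound_vote(preds)["C"] == 1

    def test_exact_tie_falls_back_to_lowest_class_index(self):
        preds = [("D", [0.6, 0.4]), ("D", [0.4, 0.6])]
        assert compound_vote(preds)["D"] == 0


def brute_force_metrics(y_true, y_pred, n_classes):
    """Independent confusion-matrix implementation used as the oracle."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    f1s, supports = [], []
    for c in range(n_classes):
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        supports.append(np.sum(y_true == c))
    supports = np.array(supports, dtype=float)
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_f1": float(np.mean(f1s)),
        "weighted_f1": float(np.sum(np.array(f1s) * supports / supports.sum())),
    }


class TestMetrics:
    def test_perfect_predictions_score_one(self):
        m = compute_metrics([0, 1, 2], [0, 1, 2], 3)
        assert m.accuracy == m.macro_f1 == m.weighted_f1 == 1.0

    def test_hand_worked_four_sample_example(self):
        m = compute_metrics([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert m.accuracy == pytest.approx(0.75)
        assert m.macro_f1 == pytest.approx((2 / 3 + 0.8) / 2, abs=1e-4)
        assert m.weighted_f1 == pytest.approx(0.7333, abs=1e-3)
        assert m.per_class_accuracy == pytest.approx([0.5, 1.0])

    def test_single_class_collapse(self):
        m = compute_metrics([0, 0, 1, 1], [0, 0, 0, 0], 2)
        assert m.accuracy == pytest.approx(0.5)
        assert m.macro_f1 == pytest.approx(1 / 3, abs=1e-9)

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            n_classes = int(rng.integers(2, 6))
            n = int(rng.integers(3, 30))
            y_true = rng.integers(0, n_classes, n)
            y_pred = rng.integers(0, n_classes, n)
            ref = brute_force_metrics(y_true, y_pred, n_classes)
            m = compute_metrics(y_true, y_pred, n_classes)
            assert m.accuracy == pytest.approx(ref["accuracy"], abs=1e-12)
            assert m.macro_f1 == pytest.approx(ref["macro_f1"], abs=1e-12)
            assert m.weighted_f1 == pytest.approx(ref["weighted_f1"], abs=1e-12)


class TestTrainBranch:
    def test_zero_learning_rate_leaves_parameters_bitwise_unchanged(self, smoke_dataset):
        cfg = TrainConfig(epochs=2, lr_fp=0.0, seed=0, batch_size=16)
        # capture params by re-initializing with the same seed inside train_branch
        res = train_branch(smoke_dataset, "fp", cfg, fp_config=SMALL_FP)
        cfg2 = TrainConfig(epochs=1, lr_fp=0.0, seed=0, batch_size=16)
        res2 = train_branch(smoke_dataset, "fp", cfg2, fp_config=SMALL_FP)
        for a, b in zip(res.model.state_arrays(), res2.model.state_arrays()):
            assert np.array_equal(a, b)

    def test_history_length_and_loss_decreases_when_learning(self, smoke_dataset):
        cfg = TrainConfig(epochs=2, lr_fp=1e-3, seed=0, batch_size=16)
        res = train_branch(smoke_dataset, "fp", cfg, fp_config=SMALL_FP)
        assert len(res.history) == 2
        assert res.history[1]["train_loss"] <= res.history[0]["train_loss"]

    def test_unknown_branch_rejected(self, smoke_dataset):
        with pytest.raises(ConfigurationError, match="branch"):
            train_branch(smoke_dataset, "xx", TrainConfig(epochs=1))

    def test_fingerprint_branch_records_representation_stats(self, smoke_dataset):
        cfg = TrainConfig(epochs=1, lr_fp=1e-3, seed=0, batch_size=16)
        res = train_branch(smoke_dataset, "fp", cfg, fp_config=SMALL_FP)
        assert set(res.repr_stats) == {"init", "trained"}
        for stats in res.repr_stats.values():
            assert set(stats) == {"mean_common_cosine", "mean_abs_offdiag"}


class TestRunProtocol:
    @pytest.fixture(scope="class")
    def report(self, smoke_dataset):
        cfg = TrainConfig(epochs=2, lr_ci=1e-3, lr_fp=1e-3, seed=7, batch_size=16)
        return run_protocol(
            smoke_dataset,
            cfg,
            backbone=BackboneConfig.tiny(),
            fp_config=SMALL_FP,
            n_folds=2,
        )

    def test_report_structure(self, report):
        assert report["n_folds"] == 2
        assert len(report["folds"]) == 2
        for fold in report["folds"]:
            assert len(fold["history_ci"]) == 2
            assert len(fold["history_fp"]) == 2
        assert set(report["test_sample_metrics"]) == {"ci", "fp", "fused"}
        assert 0.0 <= report["beta"] <= 1.0
        assert len(report["beta_grid"]) == 11

    def test_images_never_straddle_subsets(self, report, smoke_dataset):
        assignment = report["assignment"]
        for s in smoke_dataset.samples:
            assert s.compound_id in assignment

    def test_compound_level_metrics_present(self, report):
        assert 0.0 <= report["test_compound_metrics"]["accuracy"] <= 1.0

    def test_json_serializable(self, report):
        import json

        json.dumps(report)
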