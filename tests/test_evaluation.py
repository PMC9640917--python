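import numpy as np
import pandas as pd
import pytest

from mcatnet.cohort import CohortSpec, generate_cohort
from mcatnet.evaluation import (
    ExperimentSpec,
    HarnessConfig,
    MetricsReport,
    auc_z_test,
    confusion_metrics,
    hanley_mcneil_se,
    project_embeddings,
    roc_auc,
    run_cv_experiment,
    stratified_kfold,
)
from mcatnet.training import AugmentationPolicy, TrainingConfig


def brute_force_auc(labels, scores):
    """Exhaustive pairwise Mann-Whitney oracle: ties count 1/2."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedKFold:
    @staticmethod
    def records(n, n_pos, seed=0):
        spec = CohortSpec(n_ct_only=n, n_mri_only=0, n_mixed=0,
                          pos_ct_only=n_pos, pos_mri_only=0, pos_mixed=0, side=8, seed=seed)
        return generate_cohort(spec)

    def test_fold_sizes_for_49_records(self):
        split = stratified_kfold(self.records(49, 18), k=5, seed=0)
        assert sorted(len(f) for f in split.folds) == [9, 10, 10, 10, 10]

    def test_partition_properties(self):
        split = stratified_kfold(self.records(49, 18), k=5, seed=1)
        all_idx = np.concatenate(split.folds)
        assert len(all_idx) == len(set(all_idx.tolist())) == 49

    def test_label_balance_within_one(self):
        split = stratified_kfold(self.records(49, 18), k=5, seed=2)
        for fold in split.folds:
            n_pos = split.labels[fold].sum()
            assert abs(n_pos - 18 / 5) <= 1

    def test_too_few_positives_raises(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(self.records(20, 3), k=5, seed=0)

    def test_deterministic(self):
        recs = self.records(30, 12)
        a = stratified_kfold(recs, k=5, seed=3)
        b = stratified_kfold(recs, k=5, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)


class TestConfusionMetrics:
    def test_hand_computed_counts(self):
        # TP=3, FP=1, FN=1, TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4]
        m = confusion_metrics(y, p)
        assert m["counts"] == {"tp": 3, "fp": 1, "fn": 1, "tn": 5}
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = confusion_metrics([1, 0, 1], [0.9, 0.1, 0.8])
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "precision", "f1"))

    def test_no_positive_predictions_flagged(self):
        m = confusion_metrics([1, 0], [0.1, 0.2])
        assert m["degenerate"]
        assert m["precision"] == 0.0 and m["sensitivity"] == 0.0 and m["f1"] == 0.0

    def test_threshold_is_strictly_greater(self):
        m = confusion_metrics([1], [0.5])
        assert m["counts"]["fn"] == 1  # exactly 0.5 -> negative call

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_tied_pair_counts_half(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.5, 0.5, 0.1]) == pytest.approx(0.875)

    def test_all_tied_scores(self):
        assert roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 31))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    def test_complement_identity_for_tie_free_scores(self, rng):
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.permutation(20).astype(float)  # distinct
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


class TestAucZTest:
    def test_equal_aucs_zero_z(self):
        z, p = auc_z_test(0.7, 18, 31, 0.7, 18, 31)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_monotone_in_auc_gap(self):
        gaps = [0.02, 0.05, 0.1, 0.2]
        zs = [abs(auc_z_test(0.5, 20, 20, 0.5 + g, 20, 20)[0]) for g in gaps]
        assert zs == sorted(zs)

    def test_matches_independent_hanley_mcneil_oracle(self):
        # independently coded SE from the AUC-only variance approximation
        def se(a, m, n):
            q1 = a / (2 - a)
            q2 = 2 * a * a / (1 + a)
            return np.sqrt((a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n))

        z_expected = (0.69 - 0.62) / np.hypot(se(0.62, 18, 31), se(0.69, 18, 31))
        z, _ = auc_z_test(0.62, 18, 31, 0.69, 18, 31)
        assert z == pytest.approx(z_expected, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc_z_test(1.0, 10, 10, 0.5, 10, 10)
        with pytest.raises(ValueError):
            hanley_mcneil_se(0.7, 0, 10)


class TestMetricsReport:
    def test_aggregate_equals_hand_mean_sd(self):
        rows = pd.DataFrame(
            {
                "experiment": ["e"] * 5,
                "fold": range(5),
                "n_val": [10] * 5,
                "accuracy": [0.5, 0.6, 0.7, 0.8, 0.9],
                "sensitivity": [0.4, 0.5, 0.6, 0.7, 0.8],
                "precision": [0.3, 0.4, 0.5, 0.6, 0.7],
                "f1": [0.35, 0.45, 0.55, 0.65, 0.75],
                "auc": [0.55, 0.65, 0.75, 0.85, 0.95],
            }
        )
        agg = MetricsReport(rows).aggregate().iloc[0]
        assert agg["accuracy_mean"] == pytest.approx(0.7)
        assert agg["accuracy_sd"] == pytest.approx(np.std([0.5, 0.6, 0.7, 0.8, 0.9], ddof=1))
        assert agg["auc_mean"] == pytest.approx(0.75)


class TestProjection:
    def test_shape_and_determinism(self, rng):
        emb = rng.standard_normal((20, 16))
        labels = rng.integers(0, 2, 20)
        a, _ = project_embeddings(emb, labels, seed=0)
        b, _ = project_embeddings(emb, labels, seed=0)
        assert a.shape == (20, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_keep_high_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        a = rng.normal(0, 0.5, (25, 16))
        b = rng.normal(10, 0.5, (25, 16))  # inter/intra ratio ~10
        emb = np.vstack([a, b])
        labels = np.array([0] * 25 + [1] * 25)
        coords, _ = project_embeddings(emb, labels, method="pca", seed=0)
        assert silhouette_score(coords, labels) > 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            project_embeddings(np.zeros((2, 4)), [0, 1])

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            project_embeddings(rng.standard_normal((5, 3)), np.zeros(5), method="umap")


@pytest.fixture(scope="module")
def tiny_report():
    spec = CohortSpec(n_ct_only=30, n_mri_only=0, n_mixed=0,
                      pos_ct_only=12, pos_mri_only=0, pos_mixed=0, side=16, seed=6)
    records = generate_cohort(spec)
    cfg = HarnessConfig(
        policy=AugmentationPolicy(multiplicity=1),
        pretrain=TrainingConfig(stage="pretrain", epochs=1),
        finetune=TrainingConfig(stage="finetune", epochs=1),
        branch_overrides={"widths": (4, 8, 16), "embedding_dim": 8},
    )
    grid = [ExperimentSpec("CT", "mcat", "two_stage")]
    return records, cfg, grid, run_cv_experiment(records, grid, seed=0, cfg=cfg)


class TestCvHarness:
    def test_report_shape_and_ranges(self, tiny_report):
        _, _, _, report = tiny_report
        assert len(report.rows) == 5
        for m in ("accuracy", "sensitivity", "precision", "f1", "auc"):
            assert report.rows[m].between(0, 1).all()

    def test_identical_seed_reproduces_report(self, tiny_report):
        records, cfg, grid, report = tiny_report
        again = run_cv_experiment(records, grid, seed=0, cfg=cfg)
        pd.testing.assert_frame_equal(report.rows, again.rows)

    def test_invalid_experiment_specs(self):
        with pytest.raises(ValueError):
            ExperimentSpec("PET", "mcat", "two_stage")
        with pytest.raises(ValueError):
            ExperimentSpec("CT", "resnet18", "two_stage")  # baselines are end-to-end
        with pytest.raises(ValueError):
            ExperimentSpec("CT", "mcat", "transfer")
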