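import numpy as np
import pytest

from mcatnet import nn
from mcatnet.models import BranchConfig, build_single_branch
from mcatnet.training import (
    AugmentationPolicy,
    TrainingConfig,
    augment,
    build_augmented_pool,
    end_to_end_epochs_for_parity,
    finetune_classifier,
    pretrain_embedding,
    records_to_arrays,
    train_end_to_end,
)

from conftest import make_ct_stack

IDENTITY = AugmentationPolicy(
    horizontal_flip=False, vertical_flip=False, rotation_deg=0.0,
    scale_jitter=0.0, translate_frac=0.0, intensity_sd=0.0, multiplicity=1,
)


class TestAugment:
    def test_identity_policy_is_identity(self, rng):
        stack = make_ct_stack(side=16, impulse=(3, 7))
        out = augment(stack, IDENTITY, rng)
        np.testing.assert_array_equal(out.to_array(), stack.to_array())

    def test_fixed_seed_reproducible(self):
        stack = make_ct_stack(side=16, impulse=(3, 7))
        policy = AugmentationPolicy(multiplicity=1)
        a = augment(stack, policy, np.random.default_rng(42))
        b = augment(stack, policy, np.random.default_rng(42))
        np.testing.assert_array_equal(a.to_array(), b.to_array())

    def test_horizontal_flip_moves_impulse_in_every_channel(self):
        side, col = 16, 3
        stack = make_ct_stack(side=side, fill=0.0, impulse=(5, col))
        policy = AugmentationPolicy(
            horizontal_flip=True, vertical_flip=False, rotation_deg=0.0,
            scale_jitter=0.0, translate_frac=0.0, intensity_sd=0.0, multiplicity=1,
        )
        seed = next(s for s in range(100) if np.random.default_rng(s).integers(2) == 1)
        out = augment(stack, policy, np.random.default_rng(seed))
        for ch in out.to_array():
            r, c = np.unravel_index(np.argmax(ch), ch.shape)
            assert (r, c) == (5, side - 1 - col)

    def test_values_stay_in_unit_interval(self, rng):
        stack = make_ct_stack(side=16, fill=0.99)
        policy = AugmentationPolicy(intensity_sd=0.5, multiplicity=1)
        out = augment(stack, policy, rng)
        arr = out.to_array()
        assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_pool_marks_provenance(self, tiny_ct_cohort, rng):
        pool = build_augmented_pool(tiny_ct_cohort[:4], AugmentationPolicy(multiplicity=2), rng)
        assert len(pool) == 12
        assert sum(r.origin == "original" for r in pool) == 4
        assert sum(r.origin == "augmented" for r in pool) == 8

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(rotation_deg=-3)
        with pytest.raises(ValueError):
            AugmentationPolicy(multiplicity=0)


class TestTripletLoss:
    def test_satisfied_margin_is_zero(self):
        e_a, e_p, e_n = np.array([0.0, 0.0]), np.array([0.2, 0.0]), np.array([1.5, 0.0])
        assert nn.triplet_loss(e_a, e_p, e_n, margin=0.3) == pytest.approx(0.0)

    def test_violated_margin_value(self):
        # d2(a,p)=1.0, d2(a,n)=0.5 -> 1.0 - 0.5 + 0.3 = 0.8
        e_a = np.array([0.0, 0.0])
        e_p = np.array([1.0, 0.0])
        e_n = np.array([np.sqrt(0.5), 0.0])
        assert nn.triplet_loss(e_a, e_p, e_n, margin=0.3) == pytest.approx(0.8)

    def test_collapsed_triplet_returns_margin(self):
        e = np.array([0.3, -0.4])
        assert nn.triplet_loss(e, e, e, margin=0.3) == pytest.approx(0.3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nn.triplet_loss(np.zeros(3), np.zeros(2), np.zeros(3), 0.3)

    def test_zero_when_interclass_gap_exceeds_margin(self, rng):
        # same-class points clustered, other class far: every triplet satisfied
        pos = rng.normal(0, 0.01, (5, 4))
        neg = rng.normal(10, 0.01, (5, 4))
        emb = np.vstack([pos, neg])
        labels = np.array([1] * 5 + [0] * 5)
        loss, demb, _ = nn.triplet_loss_batch(emb, labels, margin=0.3, strategy="batch_all")
        assert loss == 0.0
        assert not demb.any()


class TestMining:
    def test_batch_all_enumeration(self):
        emb = np.eye(3)
        batch = nn.mine_triplets(emb, [1, 1, 0], "batch_all")
        assert sorted(batch.as_tuples()) == [(0, 1, 2), (1, 0, 2)]

    def test_single_class_raises(self):
        with pytest.raises(nn.NoValidTripletsError):
            nn.mine_triplets(np.eye(3), [1, 1, 1], "batch_all")

    def test_batch_hard_subset_of_batch_all(self, rng):
        emb = rng.standard_normal((10, 4))
        labels = rng.integers(0, 2, 10)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        hard = set(nn.mine_triplets(emb, labels, "batch_hard").as_tuples())
        full = set(nn.mine_triplets(emb, labels, "batch_all").as_tuples())
        assert hard <= full

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            nn.mine_triplets(np.eye(3), [1, 0, 1], "semi_hard")


@pytest.fixture(scope="module")
def small_branch_cfg():
    return BranchConfig(modality="CT", widths=(8, 16, 32), embedding_dim=16)


class TestPretrain:
    def test_loss_decreases(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        policy = AugmentationPolicy(multiplicity=2)
        hist = pretrain_embedding(
            net, tiny_ct_cohort, policy, TrainingConfig(stage="pretrain", epochs=8, seed=0)
        )
        assert len(hist) == 8
        assert hist[-1] < hist[0]

    def test_zero_epochs_no_change(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        before = net.get_state()
        pretrain_embedding(
            net, tiny_ct_cohort, IDENTITY, TrainingConfig(stage="pretrain", epochs=0)
        )
        for a, b in zip(before, net.get_state()):
            np.testing.assert_array_equal(a, b)

    def test_deterministic_given_seed(self, tiny_ct_cohort, small_branch_cfg):
        states = []
        for _ in range(2):
            net = build_single_branch(small_branch_cfg, seed=3)
            pretrain_embedding(
                net, tiny_ct_cohort, AugmentationPolicy(multiplicity=1),
                TrainingConfig(stage="pretrain", epochs=2, seed=7),
            )
            states.append(net.get_state())
        for a, b in zip(*states):
            np.testing.assert_array_equal(a, b)

    def test_head_untouched(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        head_before = {k: v.copy() for k, v in net.head.params.items()}
        pretrain_embedding(
            net, tiny_ct_cohort, IDENTITY, TrainingConfig(stage="pretrain", epochs=2)
        )
        for k, v in head_before.items():
            np.testing.assert_array_equal(net.head.params[k], v)

    def test_single_class_rejected(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        ones = [r for r in tiny_ct_cohort if r.label == 1]
        with pytest.raises(nn.NoValidTripletsError):
            pretrain_embedding(net, ones, IDENTITY, TrainingConfig(stage="pretrain", epochs=1))


class TestFinetune:
    def test_separable_cohort_reaches_high_training_accuracy(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        policy = AugmentationPolicy(multiplicity=2)
        pretrain_embedding(
            net, tiny_ct_cohort, policy, TrainingConfig(stage="pretrain", epochs=10, seed=0)
        )
        finetune_classifier(
            net, tiny_ct_cohort, TrainingConfig(stage="finetune", epochs=30, seed=0)
        )
        x, y = records_to_arrays(tiny_ct_cohort, "CT")
        acc = np.mean((net.predict_proba(x) > 0.5).astype(int) == y)
        assert acc >= 0.9

    def test_zero_epochs_no_change(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        before = net.get_state()
        finetune_classifier(net, tiny_ct_cohort, TrainingConfig(stage="finetune", epochs=0))
        for a, b in zip(before, net.get_state()):
            np.testing.assert_array_equal(a, b)

    def test_frozen_embedding_stays_fixed(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        refs = net.embedding_param_refs()
        snapshot = [m.params[k].copy() for m, k in refs]
        finetune_classifier(
            net, tiny_ct_cohort,
            TrainingConfig(stage="finetune", epochs=2, freeze_embedding=True),
        )
        for (m, k), old in zip(refs, snapshot):
            np.testing.assert_array_equal(m.params[k], old)

    def test_empty_and_single_class_rejected(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        with pytest.raises(ValueError, match="empty"):
            finetune_classifier(net, [], TrainingConfig(stage="finetune", epochs=1))
        ones = [r for r in tiny_ct_cohort if r.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            finetune_classifier(net, ones, TrainingConfig(stage="finetune", epochs=1))


class TestEndToEnd:
    def test_budget_parity_step_count(self):
        policy = AugmentationPolicy(multiplicity=4)
        pre = TrainingConfig(stage="pretrain", epochs=15, batch_size=32)
        fine = TrainingConfig(stage="finetune", epochs=15, batch_size=32)
        n = 71
        epochs = end_to_end_epochs_for_parity(n, policy, pre, fine)
        pool = n * 5
        steps_two_stage = 15 * int(np.ceil(pool / 32)) + 15 * int(np.ceil(n / 32))
        steps_e2e = epochs * int(np.ceil(pool / 32))
        assert abs(steps_e2e - steps_two_stage) <= int(np.ceil(pool / 32))

    def test_probabilities_valid_and_deterministic(self, tiny_ct_cohort, small_branch_cfg):
        probs = []
        for _ in range(2):
            net = build_single_branch(small_branch_cfg, seed=1)
            train_end_to_end(
                net, tiny_ct_cohort, AugmentationPolicy(multiplicity=1),
                TrainingConfig(stage="end_to_end", epochs=2, seed=5),
            )
            x, _ = records_to_arrays(tiny_ct_cohort, "CT")
            probs.append(net.predict_proba(x))
        assert np.all((probs[0] >= 0) & (probs[0] <= 1))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_stage_mismatch_rejected(self, tiny_ct_cohort, small_branch_cfg):
        net = build_single_branch(small_branch_cfg, seed=0)
        with pytest.raises(ValueError, match="stage"):
            train_end_to_end(net, tiny_ct_cohort, IDENTITY, TrainingConfig(stage="pretrain"))
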