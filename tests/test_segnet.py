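"""Segmenter architecture, snapshot training, voting and fold bookkeeping."""

import itertools

import numpy as np
import pytest

from semprep.core import ClassLabel, ClassMap, SectionImage, dice_scores
from semprep.patchwork import PatchGrid
from semprep.segnet import (
    Fold,
    FoldPlan,
    SnapshotEnsemble,
    TrainConfig,
    UNet,
    build_model,
    choose_threshold,
    ensemble_vote,
    least_overfit_fold,
    predict_section,
    section_confidence,
    train_snapshots,
)


class TestBuildModel:
    def test_default_budget_parameter_count(self):
        model = build_model(2e6)
        assert 1.5e6 <= model.param_count <= 2.5e6

    def test_impossible_budget_raises(self):
        with pytest.raises(ValueError):
            build_model(10)

    def test_predict_probabilities_sum_to_one(self, rng):
        model = UNet(base_width=2, levels=2, seed=0)
        x = rng.random((2, 16, 16), dtype=np.float32)
        p = model.predict(x)
        assert p.shape == (3, 16, 16)
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-5)

    def test_same_seed_same_outputs(self, rng):
        x = rng.random((2, 16, 16), dtype=np.float32)
        p1 = UNet(base_width=2, levels=2, seed=3).predict(x)
        p2 = UNet(base_width=2, levels=2, seed=3).predict(x)
        assert np.array_equal(p1, p2)

    def test_incompatible_window_size_rejected(self, rng):
        model = UNet(base_width=2, levels=3, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.predict(rng.random((2, 20, 20), dtype=np.float32))


def _toy_band_dataset(rng, n=6, size=16, block=4):
    """Linearly separable toy: class = intensity band of channel 0."""
    data = []
    for _ in range(n):
        base = rng.integers(0, 3, (size // block, size // block))
        base = base.repeat(block, axis=0).repeat(block, axis=1)
        x0 = (base * 100 + 25) / 255.0
        x1 = (base == 2) * 0.8
        x = np.stack([x0, x1]).astype(np.float32)
        data.append((x, base.astype(np.int64)))
    return data


class TestTraining:
    def test_loss_descends_and_snapshots_tagged(self, rng):
        data = _toy_band_dataset(rng)
        cfg = TrainConfig(epochs=10, snapshot_epochs=(8, 9, 10), seed=0)
        model = UNet(base_width=2, levels=2, seed=0)
        ens, metrics = train_snapshots(data, cfg, model=model, val=data[:2])
        assert metrics[-1]["loss"] <= metrics[0]["loss"]
        assert ens.epochs == (8, 9, 10)
        assert len(ens.members) == 3

    def test_separable_toy_reaches_high_validation_dice(self, rng):
        data = _toy_band_dataset(rng, n=8)
        cfg = TrainConfig(epochs=30, snapshot_epochs=(28, 29, 30), seed=0,
                          batch_size=2)
        model = UNet(base_width=4, levels=2, seed=0)
        _, metrics = train_snapshots(data, cfg, model=model, val=data[:3])
        assert metrics[-1]["val_dice"] >= 0.95

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_snapshots([], TrainConfig(epochs=1, snapshot_epochs=(1,)))

    def test_snapshot_epochs_validated(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=5, snapshot_epochs=(6,))


class _StubModel:
    """Deterministic stand-in producing a fixed per-window class."""

    def __init__(self, label):
        self.label = label

    def predict(self, x):
        p = np.zeros((3,) + x.shape[1:], dtype=np.float32)
        p[self.label] = 1.0
        return p


class _PixelRuleModel:
    """Translation-equivariant oracle: class = intensity band of channel 0."""

    def predict(self, x):
        labels = np.minimum((x[0] * 255).astype(int) // 86, 2)
        p = np.zeros((3,) + x.shape[1:], dtype=np.float32)
        np.put_along_axis(p, labels[None], 1.0, axis=0)
        return p


class TestPredictSection:
    def test_equivariant_oracle_round_trips_to_truth(self, rng):
        pixels = rng.integers(0, 256, (96, 96)).astype(np.uint8)
        truth = np.minimum(pixels.astype(int) // 86, 2)
        img = SectionImage(pixels, "nuclear")
        img2 = SectionImage(pixels, "lectin")
        cm, _ = predict_section(_PixelRuleModel(), img, img2, PatchGrid(64, 32, 16))
        assert np.array_equal(cm.labels, truth.astype(np.uint8))

    def test_constant_stub_gives_constant_map(self, sections):
        nuclear, lectin, _ = sections[0]
        grid = PatchGrid(64, 32, 16)
        cm, conf = predict_section(_StubModel(1), nuclear, lectin, grid)
        assert cm.shape == nuclear.shape
        assert np.all(cm.labels == 1)
        assert conf.shape == (3,) + nuclear.shape

    def test_tie_priority_normal_over_risk_over_none(self):
        class Uniform:
            def predict(self, x):
                return np.full((3,) + x.shape[1:], 1 / 3, dtype=np.float32)

        img = SectionImage(np.zeros((32, 32), np.uint8), "nuclear")
        img2 = SectionImage(np.zeros((32, 32), np.uint8), "lectin")
        cm, _ = predict_section(Uniform(), img, img2, PatchGrid(32, 16, 8))
        assert np.all(cm.labels == int(ClassLabel.NORMAL))

    def test_shape_mismatch(self, sections):
        nuclear, _, _ = sections[0]
        other = SectionImage(np.zeros((16, 16), np.uint8), "lectin")
        with pytest.raises(ValueError):
            predict_section(_StubModel(0), nuclear, other, PatchGrid(64, 32, 16))


class TestEnsembleVote:
    def brute_force_vote(self, votes, final):
        """Oracle: count votes; plurality wins; 1/1/1 tie -> final's vote."""
        counts = [votes.count(c) for c in range(3)]
        top = max(counts)
        winners = [c for c in range(3) if counts[c] == top]
        if len(winners) > 1 and final in winners:
            return final, top / 3
        return winners[0], top / 3

    def test_exhaustive_27_combinations(self):
        """Vote agrees with brute force on every 3-voter/3-class combo."""
        for votes in itertools.product(range(3), repeat=3):
            maps = [ClassMap(np.full((2, 2), v, np.uint8)) for v in votes]
            z, conf = ensemble_vote(maps, final=maps[-1])
            want_label, want_p = self.brute_force_vote(list(votes), votes[-1])
            assert np.all(z.labels == want_label), votes
            assert np.allclose(conf.proportions, want_p)
            assert conf.proportions[0, 0] in (1 / 3, 2 / 3, 1.0)

    def test_majority_and_unanimous(self):
        a = ClassMap(np.zeros((2, 2), np.uint8))
        b = ClassMap(np.full((2, 2), 1, np.uint8))
        z, conf = ensemble_vote([a, a, b])
        assert np.all(z.labels == 0) and np.all(conf.proportions == 2 / 3)
        z, conf = ensemble_vote([a, a, a])
        assert conf.mean_confidence == 1.0

    def test_three_way_tie_resolves_to_final(self):
        maps = [ClassMap(np.full((1, 1), v, np.uint8)) for v in (0, 1, 2)]
        z, conf = ensemble_vote(maps, final=maps[1])  # "risk" is most-trained
        assert z.labels[0, 0] == 1 and conf.proportions[0, 0] == pytest.approx(1 / 3)

    def test_even_member_count_rejected(self):
        a = ClassMap(np.zeros((2, 2), np.uint8))
        with pytest.raises(ValueError):
            ensemble_vote([a, a])

    def test_random_triples_against_oracle(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 3, (3, 8, 8)).astype(np.uint8)
            maps = [ClassMap(l) for l in labels]
            z, conf = ensemble_vote(maps, final=maps[-1])
            for r in range(8):
                for c in range(8):
                    want_label, want_p = self.brute_force_vote(
                        [int(l[r, c]) for l in labels], int(labels[-1][r, c])
                    )
                    assert z.labels[r, c] == want_label
                    assert conf.proportions[r, c] == pytest.approx(want_p)


class TestConfidenceAndThreshold:
    def test_section_confidence_examples(self):
        assert section_confidence(np.ones((4, 4))) == 1.0
        half = np.concatenate([np.ones(8), np.full(8, 2 / 3)]).reshape(4, 4)
        assert section_confidence(half) == pytest.approx(5 / 6)

    def test_choose_threshold_order_statistic(self):
        assert choose_threshold([0.99, 0.98, 0.97], capacity=2) == 0.98

    def test_choose_threshold_floor_dominates(self):
        assert choose_threshold([0.8, 0.7, 0.85], capacity=2) == 0.90

    def test_choose_threshold_capacity_exceeds_n(self):
        assert choose_threshold([0.95, 0.93], capacity=12) == 0.93
        assert choose_threshold([0.5, 0.93], capacity=12) == 0.90

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold([])


class TestFolds:
    def test_least_overfit_is_argmin(self):
        assert least_overfit_fold({"A": 0.9, "B": 0.8}) == "B"
        assert least_overfit_fold({"A": 0.9, "B": 0.9}) == "A"
        assert least_overfit_fold({"A": 0.5}) == "A"

    def test_fold_disjointness_enforced(self):
        with pytest.raises(ValueError):
            Fold(("a", "b"), ("b",), ("c",))

    def test_leave_one_out_plan(self):
        plan = FoldPlan.leave_one_out(["a", "b", "c", "d"])
        assert len(plan.folds) == 4
        tests = [f.test_ids[0] for f in plan.folds]
        assert sorted(tests) == ["a", "b", "c", "d"]
        for f in plan.folds:
            assert len(f.train_ids) == 2 and len(f.val_ids) == 1

    def test_partition_plan_covers_every_section_once(self):
        ids = [f"s{i}" for i in range(11)]
        plan = FoldPlan.partition(ids, n_folds=4, n_val=2, seed=1)
        tests = [sid for f in plan.folds for sid in f.test_ids]
        assert sorted(tests) == sorted(ids)

    def test_ensemble_needs_odd_members(self):
        with pytest.raises(ValueError):
            SnapshotEnsemble(members={1: object(), 2: object()})
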