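import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalseg.errors import CanalSegError
from canalseg.models import ModelSpec, build_model
from canalseg.training import (
    ClassWeights,
    PatchSpec,
    SplitSpec,
    TrainConfig,
    median_frequency_weights,
    sample_patches,
    split_dataset,
    train,
    weighted_bce,
)
from canalseg.volume_io import BinaryMask, Volume


class TestMedianFrequencyWeights:
    def test_equal_frequencies_give_unit_weights(self):
        w = median_frequency_weights(
            {"background": 500, "canal": 500}, {"background": 10, "canal": 10}, 100
        )
        assert w.weights["background"] == pytest.approx(1.0)
        assert w.weights["canal"] == pytest.approx(1.0)

    def test_hand_arithmetic_99_to_1(self):
        # freqs 0.99 and 0.01 -> median 0.5 -> weights (0.5/0.99, 0.5/0.01)
        w = median_frequency_weights(
            {"background": 9900, "canal": 100}, {"background": 10, "canal": 10}, 1000
        )
        assert w.weights["background"] == pytest.approx(0.5 / 0.99)
        assert w.weights["canal"] == pytest.approx(50.0)

    def test_rare_class_ratio_normalises_to_5_3_per_1000(self):
        """A canal:background frequency ratio of 0.0053 yields weights in
        the 5.3:1000 proportion (background:canal)."""
        w = median_frequency_weights(
            {"background": 1_000_000, "canal": 5300},
            {"background": 100, "canal": 100},
            10_000,
        )
        norm = w.normalized_to("canal", scale=1000.0)
        assert norm["background"] == pytest.approx(5.3)
        assert norm["canal"] == pytest.approx(1000.0)

    def test_zero_presence_rejected(self):
        with pytest.raises(CanalSegError):
            median_frequency_weights({"a": 10, "b": 10}, {"a": 0, "b": 1}, 100)


class TestWeightedBCE:
    def test_unit_weights_equal_plain_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=(11, 13))
        t = (rng.random((11, 13)) > 0.5).astype(float)
        reference = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
        assert weighted_bce(p, t, (1.0, 1.0)) == pytest.approx(reference, abs=1e-10)

    def test_single_canal_voxel_hand_value(self):
        # one voxel, t=1, p=0.5, canal weight 1000 -> 1000*ln 2
        loss = weighted_bce(np.array([[0.5]]), np.array([[1.0]]), (5.3, 1000.0))
        assert loss == pytest.approx(1000.0 * math.log(2.0), rel=1e-12)

    def test_perfect_prediction_hits_clipping_floor(self):
        loss = weighted_bce(np.array([[1.0]]), np.array([[1.0]]), (1.0, 1.0), eps=1e-7)
        assert loss == pytest.approx(-math.log(1 - 1e-7), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CanalSegError):
            weighted_bce(np.zeros((2, 2)) + 0.5, np.zeros((3, 2)), (1, 1))

    def test_class_weights_validator(self):
        with pytest.raises(CanalSegError):
            ClassWeights({"background": 0.0, "canal": 1.0})


class TestSplit:
    def test_paper_scale_test_partition(self):
        tr, va, te = split_dataset(49094, SplitSpec((6, 2, 2), seed=0))
        assert len(te) == 9818
        assert len(va) == 9818
        assert len(tr) == 49094 - 2 * 9818

    def test_exact_division(self):
        tr, va, te = split_dataset(10, SplitSpec((6, 2, 2), seed=1))
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_seed_reproducible(self):
        a = split_dataset(101, SplitSpec((6, 2, 2), seed=42))
        b = split_dataset(101, SplitSpec((6, 2, 2), seed=42))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 3000),
        ratio=st.tuples(st.integers(1, 9), st.integers(1, 9), st.integers(1, 9)),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_partitions_disjoint_and_exhaustive(self, n, ratio, seed):
        tr, va, te = split_dataset(n, SplitSpec(ratio, seed=seed))
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n
        total = sum(ratio)
        assert len(te) == n * ratio[2] // total
        assert len(va) == n * ratio[1] // total

    def test_stratified_balances_classes(self):
        labels = np.array([1] * 40 + [0] * 160)
        tr, va, te = split_dataset(200, SplitSpec((6, 2, 2), seed=0, stratified=True), labels)
        for part, expect in ((tr, 24), (va, 8), (te, 8)):
            assert labels[part].sum() == expect

    def test_impossible_stratification_rejected(self):
        labels = np.array([1] * 2 + [0] * 98)
        with pytest.raises(CanalSegError):
            split_dataset(100, SplitSpec((6, 2, 2), seed=0, stratified=True), labels)


class TestPatches:
    def _coded_volume(self, shape):
        x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        return Volume(x * 1e6 + y * 1e3 + z, (1, 1, 1))

    def test_patch_sized_volume_yields_unique_patch(self):
        vol = self._coded_volume((8, 8, 8))
        mask = BinaryMask(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
        patches = sample_patches(vol, mask, PatchSpec(5, (8, 8, 8)), seed=0)
        assert len(patches) == 5
        for vp, _ in patches:
            np.testing.assert_array_equal(vp, vol.data)

    def test_seed_reproducible_corners(self):
        vol = self._coded_volume((40, 40, 40))
        mask = BinaryMask(np.zeros((40, 40, 40), dtype=bool), (1, 1, 1))
        a = sample_patches(vol, mask, PatchSpec(16, (12, 12, 12)), seed=3)
        b = sample_patches(vol, mask, PatchSpec(16, (12, 12, 12)), seed=3)
        for (va, _), (vb, _) in zip(a, b):
            np.testing.assert_array_equal(va, vb)

    def test_64_patches_of_132_from_160_cube_have_corners_in_bounds(self):
        vol = self._coded_volume((160, 160, 160))
        mask = BinaryMask(np.zeros((160, 160, 160), dtype=bool), (1, 1, 1))
        patches = sample_patches(vol, mask, PatchSpec(64, (132, 132, 132)), seed=1)
        assert len(patches) == 64
        for vp, _ in patches:
            code = vp[0, 0, 0]
            corner = (int(code // 1e6), int(code % 1e6 // 1e3), int(code % 1e3))
            assert all(0 <= c <= 28 for c in corner)

    def test_mask_cropped_to_valid_output_region(self):
        vol = self._coded_volume((20, 20, 20))
        mask = BinaryMask(np.ones((20, 20, 20), dtype=bool), (1, 1, 1))
        patches = sample_patches(
            vol, mask, PatchSpec(2, (20, 20, 20)), seed=0, mask_output_size=(4, 4, 4)
        )
        for _, mp in patches:
            assert mp.shape == (4, 4, 4)

    def test_volume_smaller_than_patch_rejected(self):
        vol = self._coded_volume((8, 8, 8))
        mask = BinaryMask(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
        with pytest.raises(CanalSegError):
            sample_patches(vol, mask, PatchSpec(1, (9, 9, 9)), seed=0)


class TestTrainLoop:
    def _tiny_setup(self):
        spec = ModelSpec("unet2d", filters=(3, 4), batch_norm=False, dropout=False, seed=0)
        _, net = build_model(spec, (8, 8))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 1, 8, 8))
        t = (rng.random((2, 8, 8)) > 0.7).astype(float)
        return net, [(x, t)]

    def test_zero_epochs_leaves_parameters_unchanged(self):
        net, batches = self._tiny_setup()
        before = [p.value.copy() for p in net.params()]
        train(net, batches, TrainConfig(epochs=0))
        for p, b in zip(net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_loss_decreases_on_tiny_problem(self):
        net, batches = self._tiny_setup()
        result = train(net, batches, TrainConfig(learning_rate=1e-2, epochs=30, seed=0))
        assert result.loss_history[-1] < result.loss_history[0]

    def test_step_decay_schedule_value(self):
        # 5e-4 divided by 5 after every 5 epochs
        cfg = TrainConfig(learning_rate=5e-4, epochs=10, schedule=(5.0, 5))
        assert cfg.lr_at_epoch(0) == pytest.approx(5e-4)
        assert cfg.lr_at_epoch(4) == pytest.approx(5e-4)
        assert cfg.lr_at_epoch(5) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(10) == pytest.approx(2e-5)

    def test_best_validation_checkpoint_restored(self):
        net, batches = self._tiny_setup()
        result = train(
            net,
            batches,
            TrainConfig(learning_rate=1e-2, epochs=12, seed=0),
            valid_batches=batches,
        )
        assert result.best_epoch is not None
        assert result.valid_history[result.best_epoch] == min(result.valid_history)
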