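"""Attention rollout, gamma correction, ROI analysis, insertion curves."""

import numpy as np
import pytest

from wildface.interpret import (
    AttentionMap,
    gamma_correct,
    gradient_weighted_rollout,
    insertion_experiment,
    random_insertion_baseline,
    roi_analysis,
    rollout_from_matrices,
)
from wildface.nn.autodiff import Tensor


class TestRolloutMatrices:
    def test_two_token_identity_attention_by_hand(self):
        # A = I with unit gradients: weighted = I, corrected = rownorm(2I) = I
        attn = np.eye(2)[None]  # one head
        grad = np.ones((1, 2, 2))
        rollout = rollout_from_matrices([attn], [grad])
        assert np.allclose(rollout, np.eye(2))

    def test_matches_literal_oracle_on_tiny_backbone(self, tiny_recognizer):
        """Independent transcription: per layer clamp/average/correct/normalize,
        then explicit left-multiplication, compared at 1e-6."""
        x = np.random.default_rng(0).random((1, 32, 32, 3)) * 2 - 1
        out = tiny_recognizer.forward(x, capture_attn=True)
        tiny_recognizer.zero_grad()
        out.logits[(0, 1)].backward()
        attns = [a.data[0] for a in out.attentions]
        grads = [a.grad[0] for a in out.attentions]

        t = attns[0].shape[-1]
        expected = np.eye(t)
        for a, g in zip(attns, grads):
            weighted = np.clip(g * a, 0.0, None).mean(axis=0) + np.eye(t)
            weighted /= weighted.sum(axis=1)[:, None]
            expected = weighted @ expected
        assert np.allclose(rollout_from_matrices(attns, grads), expected, atol=1e-6)


class TestGradientWeightedRollout:
    def test_map_normalized_to_unit_interval(self, tiny_recognizer):
        img = np.random.default_rng(1).random((32, 32, 3))
        amap = gradient_weighted_rollout(tiny_recognizer, img, 0)
        assert amap.values.shape == (32, 32)
        assert amap.values.min() == 0.0
        assert amap.values.max() == pytest.approx(1.0)

    def test_target_class_out_of_range(self, tiny_recognizer):
        with pytest.raises(ValueError, match="out of range"):
            gradient_weighted_rollout(tiny_recognizer, np.zeros((32, 32, 3)), 7)


class TestGammaCorrect:
    def test_gamma_one_is_identity(self):
        amap = AttentionMap(np.random.default_rng(0).random((8, 8)), 0)
        assert np.array_equal(gamma_correct(amap, 1.0).values, amap.values)

    def test_power_arithmetic(self):
        amap = AttentionMap(np.array([[0.25]]), 0)
        assert gamma_correct(amap, 0.5).values[0, 0] == pytest.approx(0.5)

    def test_rank_preserving(self):
        values = np.random.default_rng(2).random((10, 10))
        amap = AttentionMap(values, 0)
        for gamma in (0.7, 1.5):
            corrected = gamma_correct(amap, gamma)
            assert np.array_equal(np.argsort(values.ravel()), np.argsort(corrected.values.ravel()))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(AttentionMap(np.zeros((2, 2)), 0), 0.0)


class TestRoiAnalysis:
    def test_counting(self):
        values = np.zeros((10, 10))
        values[:5, :5] = 1.0  # exactly 25% of pixels
        report = roi_analysis(AttentionMap(values, 0), threshold=0.30)
        assert report.area_fraction == pytest.approx(0.25)

    def test_constant_below_threshold(self):
        report = roi_analysis(AttentionMap(np.full((6, 6), 0.2), 0), threshold=0.30)
        assert report.area_fraction == 0.0

    def test_overlap_with_mask(self):
        values = np.zeros((4, 4))
        values[0, :] = 1.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        report = roi_analysis(AttentionMap(values, 0), face_mask=mask)
        assert report.overlap_with_mask == pytest.approx(0.5)

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            roi_analysis(AttentionMap(np.zeros((4, 4)), 0), face_mask=np.zeros((2, 2), dtype=bool))


class _ConstantModel:
    """Stub recognizer emitting fixed logits for any input."""

    def __init__(self, logits):
        self._logits = np.asarray(logits, dtype=np.float64)
        self.n_classes = len(logits)

    def forward(self, images, train_mode=False, capture_attn=False, rng=None):
        class Out:
            pass

        out = Out()
        out.logits = Tensor(np.tile(self._logits, (images.shape[0], 1)))
        return out


class TestInsertion:
    def test_constant_model_auc_equals_its_confidence(self):
        model = _ConstantModel([0.3, 1.2, -0.5])
        conf = np.exp(1.2) / np.exp([0.3, 1.2, -0.5]).sum()
        amap = AttentionMap(np.random.default_rng(0).random((16, 16)), 1)
        curve = insertion_experiment(model, np.random.default_rng(1).random((16, 16, 3)), amap)
        assert np.allclose(curve.confidences, conf)
        assert curve.auc == pytest.approx(conf, abs=1e-12)

    def test_full_restoration_recovers_original_confidence(self, tiny_recognizer):
        from wildface.interpret import _confidence
        from wildface.training import normalize_batch

        img = np.random.default_rng(3).random((32, 32, 3))
        amap = gradient_weighted_rollout(tiny_recognizer, img, 0)
        curve = insertion_experiment(tiny_recognizer, img, amap, blur_sigma=4.0)
        orig = _confidence(tiny_recognizer, img, 0)
        assert curve.confidences[-1] == pytest.approx(orig, abs=1e-12)

    def test_auc_is_trapezoid_of_curve(self, tiny_recognizer):
        img = np.random.default_rng(4).random((32, 32, 3))
        amap = gradient_weighted_rollout(tiny_recognizer, img, 1)
        curve = insertion_experiment(tiny_recognizer, img, amap, blur_sigma=4.0)
        assert curve.auc == pytest.approx(np.trapezoid(curve.confidences, curve.fractions))
        assert 0.0 <= curve.auc <= 1.0

    def test_fraction_grid_validation(self, tiny_recognizer):
        img = np.zeros((32, 32, 3))
        amap = AttentionMap(np.random.default_rng(0).random((32, 32)), 0)
        with pytest.raises(ValueError, match="1.0"):
            insertion_experiment(tiny_recognizer, img, amap, fractions_grid=[0.0, 0.5])
        with pytest.raises(ValueError, match="increasing"):
            insertion_experiment(tiny_recognizer, img, amap, fractions_grid=[0.0, 0.5, 0.5, 1.0])

    def test_gamma_correction_leaves_insertion_auc_unchanged(self, tiny_recognizer):
        img = np.random.default_rng(5).random((32, 32, 3))
        amap = gradient_weighted_rollout(tiny_recognizer, img, 2)
        sharp = gamma_correct(amap, 1.5)
        c1 = insertion_experiment(tiny_recognizer, img, amap, blur_sigma=4.0)
        c2 = insertion_experiment(tiny_recognizer, img, sharp, blur_sigma=4.0)
        assert np.array_equal(c1.confidences, c2.confidences)
        assert c1.auc == c2.auc

    def test_random_baseline_deterministic_given_seed(self, tiny_recognizer):
        img = np.random.default_rng(6).random((32, 32, 3))
        c1 = random_insertion_baseline(tiny_recognizer, img, 0, np.random.default_rng(9), blur_sigma=4.0)
        c2 = random_insertion_baseline(tiny_recognizer, img, 0, np.random.default_rng(9), blur_sigma=4.0)
        assert np.array_equal(c1.confidences, c2.confidences)


class TestTrainedModelAttention:
    def test_attention_concentrates_on_face_region(self, benchmark_fit):
        """ROI overlap with the generative face mask must beat the permuted-map
        (spatially random attention) baseline on a trained model."""
        from wildface.augment import eval_preprocess

        model, _, results = benchmark_fit
        te = model.test_ds
        rng = np.random.default_rng(0)
        better = 0
        n_imgs = 6
        for i in range(n_imgs):
            img, cls = te.get_image(i), int(te.labels[i])
            amap = results.attention_map(img, cls, gamma=1.5)
            mask3 = np.repeat(te.masks[i][:, :, None], 3, axis=2).astype(float)
            mask = eval_preprocess(mask3, model.train_cfg.augment)[:, :, 0] > 0.5
            true_roi = roi_analysis(amap, face_mask=mask)
            perm = AttentionMap(
                amap.values.ravel()[rng.permutation(amap.values.size)].reshape(amap.values.shape),
                cls,
            )
            perm_roi = roi_analysis(perm, face_mask=mask)
            if (true_roi.overlap_with_mask or 0.0) >= (perm_roi.overlap_with_mask or 0.0):
                better += 1
        assert better >= n_imgs - 1
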