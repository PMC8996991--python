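"""Boosting weights, focusing sampling, boosted augmentation."""

import numpy as np
import pytest

import tmaboost as tb
from tmaboost.boost_train import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    AugmentRecipe,
    BoostConfig,
    ThresholdLearner,
    WeightedSample,
    boost_fit,
    boosted_augment,
    build_ignore_mask,
    init_weights,
    masked_pixel_error,
    update_weights,
)


def _labels(shape, n_pos, n_neg=0):
    lab = np.full(shape, UNKNOWN, dtype=np.int8)
    lab.flat[:n_pos] = POSITIVE
    lab.flat[n_pos : n_pos + n_neg] = NEGATIVE
    return lab


class TestInitWeights:
    def test_ten_percent_positive_tile_weighted(self):
        # 26,215 positive pixels of a 512x512 tile is ~10% coverage
        lab = _labels((512, 512), 26_215)
        assert init_weights([lab], alpha=0.05)[0] == 1.0

    def test_zero_positive_unweighted(self):
        assert init_weights([_labels((64, 64), 0)], alpha=0.05)[0] == 0.0

    def test_boundary_fraction_included(self):
        # coverage exactly alpha qualifies (>= rule)
        lab = _labels((10, 10), 5)
        assert init_weights([lab], alpha=0.05)[0] == 1.0
        lab4 = _labels((10, 10), 4)
        assert init_weights([lab4], alpha=0.05)[0] == 0.0


class TestUpdateWeights:
    def test_increment_on_misclassified_fraction(self):
        lab = np.zeros((10, 10), dtype=np.int8)
        pred = lab.copy()
        pred.flat[:10] = POSITIVE  # 10% misclassified
        w = update_weights(np.array([1.0]), [pred], [lab], alpha=0.05, chi=1.0)
        assert w[0] == 2.0

    def test_perfect_prediction_unchanged(self):
        lab = _labels((10, 10), 30, 70)
        w = update_weights(np.array([1.0]), [lab.copy()], [lab], 0.05, 1.0)
        assert w[0] == 1.0

    def test_boundary_fraction_incremented(self):
        lab = np.zeros((10, 10), dtype=np.int8)
        pred = lab.copy()
        pred.flat[:5] = POSITIVE  # exactly alpha
        w = update_weights(np.array([2.0]), [pred], [lab], alpha=0.05, chi=0.5)
        assert w[0] == 2.5

    def test_ignored_pixels_never_count_as_errors(self):
        lab = _labels((10, 10), 0, 0)  # fully unknown
        pred = np.ones((10, 10), dtype=np.int8)
        w = update_weights(np.array([1.0]), [pred], [lab], 0.05, 1.0)
        assert w[0] == 1.0

    def test_weights_nondecreasing_over_rounds(self, rng):
        labs = [rng.integers(-1, 2, (16, 16)).astype(np.int8) for _ in range(10)]
        w = init_weights(labs, 0.05)
        for _ in range(4):
            preds = [rng.integers(0, 2, (16, 16)).astype(np.int8) for _ in range(10)]
            w2 = update_weights(w, preds, labs, 0.05, 1.0)
            assert np.all(w2 >= w)
            w = w2


class TestIgnoreMask:
    def test_mask_marks_unknown_only(self):
        lab = _labels((8, 8), 10, 20)
        m = build_ignore_mask(lab)
        assert m.sum() == 64 - 30
        assert not build_ignore_mask(np.zeros((4, 4), dtype=np.int8)).any()
        assert build_ignore_mask(np.full((4, 4), UNKNOWN, dtype=np.int8)).all()

    def test_masked_loss_equals_loss_on_unmasked_half(self):
        # constant prediction on a half-masked tile: the loss must equal
        # the plain loss recomputed on the unmasked half alone
        lab = np.zeros((10, 10), dtype=np.int8)
        lab[:, :5] = UNKNOWN
        lab[:, 5:] = POSITIVE
        pred = np.zeros((10, 10), dtype=np.int8)  # constant 'negative'
        masked = masked_pixel_error(pred, lab)
        half = lab[:, 5:]
        direct = float(np.mean(pred[:, 5:] != half))
        assert masked == direct == 1.0


class TestBoostedAugment:
    def _sample(self, seed=0, weight=2.0):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        lab = rng.integers(-1, 2, (32, 32)).astype(np.int8)
        return WeightedSample(px, lab, weight=weight, tile_id="t0")

    def test_boosted_tile_gets_ten_variants(self):
        s = self._sample(weight=2.0)
        out = boosted_augment([s], init_w=np.array([1.0]), seed=5)
        assert len(out) == 11  # original + 10 geometric variants

    def test_unboosted_passthrough(self):
        s = self._sample(weight=1.0)
        out = boosted_augment([s], init_w=np.array([1.0]), seed=5)
        assert len(out) == 1 and out[0] is s

    def test_deterministic_under_seed(self):
        a = boosted_augment([self._sample()], np.array([1.0]), seed=9)
        b = boosted_augment([self._sample()], np.array([1.0]), seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)
            np.testing.assert_array_equal(sa.labels, sb.labels)

    def test_labels_follow_geometry(self):
        s = self._sample()
        out = boosted_augment([s], np.array([1.0]), seed=1)
        by_id = {o.tile_id: o for o in out}
        # 90-degree variant: labels are the same rotation of the source labels
        v90 = next(v for k, v in by_id.items() if k.endswith("+v5"))
        np.testing.assert_array_equal(v90.labels, np.rot90(s.labels, 1))
        vflip = next(v for k, v in by_id.items() if k.endswith("+v8"))
        np.testing.assert_array_equal(vflip.labels, np.flip(s.labels, axis=1))

    def test_out_of_range_jitter_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            r = AugmentRecipe(brightness_range=0.5)
        assert r.brightness_range == 0.125


class TestBoostFit:
    def _separable_samples(self, n=12, seed=0):
        """Tiles where brown index > 0 is exactly the positive class."""
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(n):
            px = np.zeros((16, 16, 3), dtype=np.uint8)
            lab = np.zeros((16, 16), dtype=np.int8)
            pos = rng.random((16, 16)) < 0.5
            px[pos] = (150, 120, 60)   # brown
            px[~pos] = (120, 120, 200)  # bluish
            lab[pos] = POSITIVE
            samples.append(WeightedSample(px, lab, weight=1.0, tile_id=f"t{i}"))
        return samples

    def test_single_round_is_one_weighted_fit(self):
        samples = self._separable_samples()
        res = boost_fit(ThresholdLearner(), samples, BoostConfig(num_rounds=1))
        direct = ThresholdLearner().fit(
            [WeightedSample(s.pixels, s.labels, 1.0) for s in samples]
        )
        assert res.model.threshold == direct.threshold
        assert res.weight_history.shape[0] == 2

    def test_training_error_not_worse_after_boosting(self):
        samples = self._separable_samples()
        res = boost_fit(ThresholdLearner(), samples, BoostConfig(num_rounds=2))
        assert res.error_history[1] <= res.error_history[0] + 1e-12

    def test_no_supervision_errors(self):
        px = np.zeros((8, 8, 3), dtype=np.uint8)
        lab = np.full((8, 8), UNKNOWN, dtype=np.int8)
        with pytest.raises(ValueError, match="no supervised signal"):
            boost_fit(ThresholdLearner(), [WeightedSample(px, lab)], BoostConfig())

    def test_zero_weight_samples_do_not_move_the_stump(self):
        samples = self._separable_samples()
        # an adversarial tile with inverted labels but no annotation mass
        adv = WeightedSample(
            samples[0].pixels.copy(),
            np.where(samples[0].labels == POSITIVE, NEGATIVE, POSITIVE).astype(np.int8),
        )
        adv.weight = 0.0
        with_adv = ThresholdLearner().fit(list(samples) + [adv])
        without = ThresholdLearner().fit(samples)
        assert with_adv.threshold == without.threshold
        assert with_adv.polarity == without.polarity
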