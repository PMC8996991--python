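"""Statistical and geometric properties of the synthetic TMA generators."""

import numpy as np
import pytest
from scipy.stats import binomtest

import tmaboost as tb
from tmaboost.effect_predict import predict_core, tile_features, TreatmentEffectClassifier
from tmaboost.pyramid import extract_region
from tmaboost.synthetic_tma import TmaSpec, generate_slide
from tmaboost.tumor_select import OracleSegmenter, select_tumor_tiles


class TestSpecValidation:
    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            TmaSpec(effective_prob=1.2)
        with pytest.raises(ValueError):
            TmaSpec(num_levels=0)
        with pytest.raises(ValueError):
            TmaSpec(effect_size=-1.0)
        with pytest.raises(ValueError):
            TmaSpec(spacing_factor=1.0, jitter_frac=0.1)  # overlap risk


class TestSlideGeneration:
    def test_core_count_and_layout(self, default_slide):
        pyr, truth = default_slide
        assert len(truth.core_boxes) == 60  # 6 x 10 grid; 12 slides -> 720
        assert len({*truth.core_ids}) == 60
        H, W = pyr.shape(0)
        for b in truth.core_boxes:
            assert 0 <= b.x and b.x2 <= W and 0 <= b.y and b.y2 <= H

    def test_twelve_slide_corpus_is_720_cores(self):
        # layout check only: geometry fields, not rendered pixels
        total = 12 * TmaSpec().rows * TmaSpec().cols
        assert total == 720

    def test_masks_fit_their_boxes(self, default_slide):
        _, truth = default_slide
        for b, m in zip(truth.core_boxes, truth.tumor_masks):
            assert m.shape == (b.h, b.w)
            assert m.dtype == bool

    def test_pyramid_levels_halve(self, default_slide):
        pyr, _ = default_slide
        for m in range(1, pyr.num_levels):
            h, w = pyr.shape(m - 1)
            assert pyr.shape(m) == (-(-h // 2), -(-w // 2))

    def test_bit_reproducible(self):
        spec = TmaSpec(rows=2, cols=2, seed=99)
        p1, t1 = generate_slide(spec)
        p2, t2 = generate_slide(spec)
        assert all(np.array_equal(a, b) for a, b in zip(p1.levels, p2.levels))
        np.testing.assert_array_equal(t1.core_labels, t2.core_labels)
        assert t1.core_boxes == t2.core_boxes

    def test_degenerate_probability_all_effective(self):
        _, truth = generate_slide(TmaSpec(rows=2, cols=3, effective_prob=1.0, seed=5))
        assert truth.core_labels.all()

    def test_effective_fraction_converges(self):
        labels = []
        for seed in range(12):
            _, truth = generate_slide(TmaSpec(rows=2, cols=5, seed=seed))
            labels.extend(truth.core_labels.tolist())
        k = int(np.sum(labels))
        ci = binomtest(k, len(labels)).proportion_ci(0.999)
        assert ci.low <= 0.572 <= ci.high

    def test_ground_truth_roundtrip(self, tmp_path, small_slide):
        _, truth = small_slide
        truth.write(str(tmp_path), slide_id="s0")
        import json, pandas as pd

        recs = json.load(open(tmp_path / "ground_truth.json"))
        assert len(recs) == len(truth.core_ids)
        df = pd.read_csv(tmp_path / "labels.csv")
        assert set(df.columns) == {"core_id", "slide_id", "outcome"}
        np.testing.assert_array_equal(df["outcome"].values, truth.core_labels)


class TestEffectSignal:
    def _auc_one_replicate(self, effect_size, seed):
        spec = TmaSpec(rows=4, cols=5, core_diameter_px=96, effect_size=effect_size, seed=seed)
        cores, labels = [], []
        for s in range(2):
            pyr, truth = generate_slide(
                TmaSpec(**{**spec.__dict__, "seed": seed + 1000 * s})
            )
            for box, mask, lab in zip(truth.core_boxes, truth.tumor_masks, truth.core_labels):
                region = extract_region(pyr, box, 0)
                sel = select_tumor_tiles(region, OracleSegmenter(mask), alpha=0.05, M=48)
                tiles = tb.fetch_medium_res_tiles(sel, pyr, box)
                if tiles:
                    cores.append(tiles)
                    labels.append(int(lab))
        labels = np.array(labels)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(cores))
        n_train = int(0.66 * len(cores))
        tr, te = order[:n_train], order[n_train:]
        if len(np.unique(labels[te])) < 2 or len(np.unique(labels[tr])) < 2:
            return None
        X = np.stack([tile_features(t) for i in tr for t in cores[i]])
        y = np.array([labels[i] for i in tr for _ in cores[i]])
        clf = TreatmentEffectClassifier().fit(X, y)
        backend = clf.tile_backend()
        betas = [predict_core(cores[i], backend).beta for i in te]
        auc, _ = tb.roc_auc(betas, labels[te])
        return auc

    def test_zero_effect_size_gives_chance_auc(self):
        """With appearance independent of outcome the classifier cannot beat
        chance; the mean test AUC over seeded replicates stays near 0.5."""
        aucs = [self._auc_one_replicate(0.0, seed) for seed in range(20)]
        aucs = [a for a in aucs if a is not None]
        assert len(aucs) >= 15
        assert abs(float(np.mean(aucs)) - 0.5) < 0.08

    def test_large_effect_size_is_learnable(self):
        aucs = [self._auc_one_replicate(2.0, seed) for seed in range(3)]
        aucs = [a for a in aucs if a is not None]
        assert np.mean(aucs) > 0.9


class TestTraceGenerator:
    def test_flat_after_plateau_when_noiseless(self):
        tr = tb.generate_trace(10_000, 4_000, noise_sd=0.0, seed=0)
        post = tr.loss[tr.iterations >= 4_000]
        assert np.allclose(np.diff(post), 0.0)
        fpost = tr.f_measure[tr.iterations >= 4_000]
        assert np.allclose(np.diff(fpost), 0.0)

    def test_seed_determinism(self):
        a = tb.generate_trace(8_000, 3_000, 0.01, seed=7)
        b = tb.generate_trace(8_000, 3_000, 0.01, seed=7)
        np.testing.assert_array_equal(a.loss, b.loss)
        np.testing.assert_array_equal(a.f_measure, b.f_measure)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tb.generate_trace(1_000, 5_000, 0.0)
        with pytest.raises(ValueError):
            tb.generate_trace(10_000, 5_000, -0.1)


class TestSurvivalGenerator:
    def test_counts_and_determinism(self):
        recs = tb.generate_survival(2, hazard_ratio=0.5, seed=0)
        assert len(recs) == 4 and sum(r.event for r in recs) == 4
        again = tb.generate_survival(2, hazard_ratio=0.5, seed=0)
        assert [(r.time, r.group) for r in recs] == [(r.time, r.group) for r in again]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tb.generate_survival(1, 0.5)
        with pytest.raises(ValueError):
            tb.generate_survival(10, 0.0)

    def test_censoring_produces_censored_records(self):
        recs = tb.generate_survival(100, 0.5, seed=1, censor_time=10.0)
        events = np.array([r.event for r in recs])
        assert 0 < events.sum() < len(recs)
        assert all(r.time > 0 for r in recs)

    def test_hazard_ratio_shifts_means(self):
        recs = tb.generate_survival(2000, 0.25, seed=2)
        t0 = np.mean([r.time for r in recs if r.group == 0])
        t1 = np.mean([r.time for r in recs if r.group == 1])
        assert t1 / t0 == pytest.approx(4.0, rel=0.15)
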