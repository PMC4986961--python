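import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from fruitpheno.core_io import Scene
from fruitpheno.segmentation import (
    PixelClassifier,
    ThresholdSpec,
    TrainingError,
    ingest_training_swatches,
    pixel_table_from_arrays,
    segment_threshold,
    segment_with_classifier,
    train_pixel_classifier,
)


def _scene_from_blue(blue):
    px = np.zeros(blue.shape + (3,), dtype=np.uint8)
    px[:, :, 2] = blue
    return Scene(pixels=px)


class TestThreshold:
    def test_blue_channel_darker(self):
        scene = _scene_from_blue(np.array([[10, 200], [200, 10]], dtype=np.uint8))
        mask = segment_threshold(scene, ThresholdSpec(("B",), (50,), "object_darker"))
        assert np.array_equal(mask.bits, [[True, False], [False, True]])

    def test_uniform_white_gives_empty_mask(self):
        scene = Scene(pixels=np.full((8, 8, 3), 255, dtype=np.uint8))
        mask = segment_threshold(scene, ThresholdSpec(("B",), (50,)))
        assert not mask.bits.any()

    def test_polarity_lighter(self):
        scene = _scene_from_blue(np.array([[10, 200], [200, 10]], dtype=np.uint8))
        mask = segment_threshold(scene, ThresholdSpec(("B",), (50,), "object_lighter"))
        assert np.array_equal(mask.bits, [[False, True], [True, False]])

    def test_multichannel_is_conjunction(self):
        px = np.full((2, 3, 3), 255, dtype=np.uint8)
        px[0, 0] = (10, 10, 10)   # dark in both R and B
        px[0, 1] = (10, 10, 200)  # dark in R only
        px[0, 2] = (200, 10, 10)  # dark in B only
        mask = segment_threshold(
            Scene(pixels=px), ThresholdSpec(("R", "B"), (50, 50))
        )
        assert mask.bits.tolist() == [[True, False, False], [False, False, False]]

    def test_ground_truth_jaccard(self, batch_scene):
        """Dark fruit on a white mat, blue cutoff 50: near-exact recovery."""
        _, scene, gt_mask, _ = batch_scene
        mask = segment_threshold(scene, ThresholdSpec(("B",), (50,)))
        inter = (mask.bits & gt_mask.bits).sum()
        union = (mask.bits | gt_mask.bits).sum()
        assert inter / union >= 0.98

    def test_idempotent_and_deterministic(self):
        rng = np.random.default_rng(3)
        scene = Scene(pixels=rng.integers(0, 256, (16, 16, 3), dtype=np.uint8))
        spec = ThresholdSpec(("B",), (128,))
        m1 = segment_threshold(scene, spec)
        m2 = segment_threshold(scene, spec)
        assert np.array_equal(m1.bits, m2.bits)

    @given(cut_lo=st.integers(0, 254), delta=st.integers(1, 128), seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_cutoff(self, cut_lo, delta, seed):
        """For dark objects, raising the cutoff never removes foreground."""
        rng = np.random.default_rng(seed)
        scene = Scene(pixels=rng.integers(0, 256, (12, 12, 3), dtype=np.uint8))
        lo = segment_threshold(scene, ThresholdSpec(("B",), (cut_lo,)))
        hi = segment_threshold(
            scene, ThresholdSpec(("B",), (min(255, cut_lo + delta),))
        )
        assert (lo.bits <= hi.bits).all()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ThresholdSpec((), ())
        with pytest.raises(ValueError):
            ThresholdSpec(("B", "B"), (10, 20))
        with pytest.raises(ValueError):
            ThresholdSpec(("B",), (300,))


class TestSwatchIngestion:
    def _swatch(self, path, color, size=(10, 10)):
        arr = np.full(size + (3,), color, dtype=np.uint8)
        Image.fromarray(arr).save(path)
        return path

    def test_two_swatches_pool_to_200_rows(self, tmp_path):
        bg = self._swatch(tmp_path / "bg.png", 250)
        fruit = self._swatch(tmp_path / "fruit.png", 40)
        table = ingest_training_swatches([bg, fruit], ["background", "fruit"])
        assert len(table) == 200
        labels, counts = np.unique(table["label"].astype(str), return_counts=True)
        assert dict(zip(labels, counts)) == {"background": 100, "fruit": 100}

    def test_three_classes_supported(self, tmp_path):
        paths = [
            self._swatch(tmp_path / "bg.png", 250),
            self._swatch(tmp_path / "dark.png", 40),
            self._swatch(tmp_path / "light.png", 180),
        ]
        table = ingest_training_swatches(paths, ["background", "dark_side", "light_side"])
        assert len(np.unique(table["label"].astype(str))) == 3

    def test_single_swatch_rejected(self, tmp_path):
        bg = self._swatch(tmp_path / "bg.png", 250)
        with pytest.raises(TrainingError):
            ingest_training_swatches([bg], ["background"])

    def test_background_label_required(self, tmp_path):
        a = self._swatch(tmp_path / "a.png", 250)
        b = self._swatch(tmp_path / "b.png", 40)
        with pytest.raises(TrainingError):
            ingest_training_swatches([a, b], ["mat", "fruit"])


class TestClassifierTraining:
    def test_split_sizes_exact(self, white_red_classifier):
        rep = white_red_classifier.training_report
        assert rep["n_pixels_total"] == 10_000
        assert rep["split_sizes"] == [7000, 1500, 1500]
        assert rep["split_fractions"] == [0.70, 0.15, 0.15]

    def test_separable_classes_reach_perfect_test_accuracy(self, white_red_classifier):
        assert white_red_classifier.training_report["test_accuracy"] == 1.0

    def test_architecture(self, white_red_classifier):
        assert white_red_classifier.coefs[0].shape == (3, 10)
        assert white_red_classifier.class_labels[0] == "background"

    def test_probabilities_sum_to_one(self, white_red_classifier):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (500, 3))
        probs = white_red_classifier.predict_proba(rgb)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_training_is_bit_reproducible(self, separable_pixel_table):
        a = train_pixel_classifier(separable_pixel_table, seed=7)
        b = train_pixel_classifier(separable_pixel_table, seed=7)
        for ca, cb in zip(a.coefs, b.coefs):
            assert np.array_equal(ca, cb)
        assert a.training_report == b.training_report

    def test_too_few_classes_or_pixels(self):
        table = pixel_table_from_arrays(
            np.zeros((200, 3), dtype=np.uint8), ["background"] * 200
        )
        with pytest.raises(TrainingError):
            train_pixel_classifier(table)
        table2 = pixel_table_from_arrays(
            np.zeros((150, 3), dtype=np.uint8), ["background"] * 100 + ["fruit"] * 50
        )
        with pytest.raises(TrainingError):
            train_pixel_classifier(table2)

    def test_save_load_roundtrip(self, white_red_classifier, tmp_path):
        p = tmp_path / "clf.json"
        white_red_classifier.save(p)
        back = PixelClassifier.load(p)
        rgb = np.array([[250, 250, 250], [150, 28, 38]])
        assert np.allclose(
            back.predict_proba(rgb), white_red_classifier.predict_proba(rgb)
        )


class TestNeuralSegmentation:
    def test_white_pixel_is_background(self, white_red_classifier):
        scene = Scene(pixels=np.full((2, 2, 3), 250, dtype=np.uint8))
        mask = segment_with_classifier(scene, white_red_classifier)
        assert not mask.bits.any()

    def test_neural_vs_threshold_agreement(self, batch_scene, white_red_classifier):
        _, scene, _, _ = batch_scene
        thr = segment_threshold(scene, ThresholdSpec(("B",), (50,)))
        neu = segment_with_classifier(scene, white_red_classifier)
        jacc = (thr.bits & neu.bits).sum() / (thr.bits | neu.bits).sum()
        assert jacc >= 0.98
        assert neu.provenance == "neural"

    def test_foreground_is_union_of_nonbackground_classes(self):
        """With two fruit-colour classes, either one counts as foreground."""
        rng = np.random.default_rng(2)
        white = np.clip(rng.normal(250, 2, (500, 3)), 0, 255).astype(np.uint8)
        dark = np.clip(rng.normal([120, 20, 30], 3, (500, 3)), 0, 255).astype(np.uint8)
        light = np.clip(rng.normal([220, 180, 60], 3, (500, 3)), 0, 255).astype(np.uint8)
        table = pixel_table_from_arrays(
            np.vstack([white, dark, light]),
            ["background"] * 500 + ["dark_side"] * 500 + ["light_side"] * 500,
        )
        clf = train_pixel_classifier(table, seed=3)
        px = np.full((2, 3, 3), 250, dtype=np.uint8)
        px[0, 0] = (250, 250, 250)
        px[0, 1] = (120, 20, 30)
        px[0, 2] = (220, 180, 60)
        mask = segment_with_classifier(Scene(pixels=px), clf)
        assert mask.bits[0].tolist() == [False, True, True]
        assert not mask.bits[1].any()
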