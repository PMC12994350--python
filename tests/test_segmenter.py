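"""Patch extraction, training, dense inference, evaluation, CV."""

import numpy as np
import pytest

import stromalyzer as st
from stromalyzer.classes import TISSUE_CLASSES, TissueClass
from stromalyzer.errors import (EmptyEvaluationError, FoldError,
                                MissingClassError, ParameterError)
from stromalyzer.segmenter import (CrossValResult, evaluate_segmentation,
                                   load_model, metrics_from_confusion,
                                   save_model, tissue_background_mask)


class TestExtractPatches:
    def test_single_class_tile_single_stride_yields_one_patch(self):
        t = st.generate_tile({TissueClass.STROMA}, 256, 0.455, seed=1)
        patches = st.extract_patches(t, stride=256)
        assert len(patches) == 1
        assert patches[0][1] == TissueClass.STROMA

    def test_grid_arithmetic(self):
        # floor((512-256)/128)+1 = 3 positions per axis
        t = st.generate_tile({TissueClass.TUMOR}, 512, 0.455, seed=2)
        assert len(st.extract_patches(t, stride=128)) == 9

    def test_full_purity_on_boundary_tile_yields_nothing(self):
        mask = np.zeros((256, 256), np.uint8)
        mask[:, 1::2] = TissueClass.STROMA  # boundary through every center
        t = st.LabeledTile(image=np.zeros((256, 256, 3), np.uint8),
                           mask=mask, spacing_um=0.455, seed=0)
        assert st.extract_patches(t, stride=64, purity_threshold=1.0) == []

    def test_undersized_tile_yields_empty_sequence(self):
        t = st.generate_tile({0}, 128, 0.455, seed=3)
        assert st.extract_patches(t, stride=64) == []

    def test_invalid_threshold_rejected(self):
        t = st.generate_tile({0}, 256, 0.455, seed=3)
        with pytest.raises(ParameterError):
            st.extract_patches(t, stride=64, purity_threshold=0.0)


class TestTraining:
    def test_heldout_accuracy_on_separable_textures(self, trained_model):
        assert trained_model.history[-1]["val_accuracy"] >= 0.95
        assert len(trained_model.history) == trained_model.config.epochs

    def test_missing_class_is_a_named_error(self):
        tiles = [st.generate_tile({TissueClass.TUMOR}, 384, 0.455, seed=1)]
        with pytest.raises(MissingClassError, match="stroma"):
            st.train_segmenter(tiles, st.TrainConfig(epochs=2), seed=0)

    def test_same_seed_same_final_loss(self):
        tiles = [st.generate_tile({int(c)}, 384, 0.455, seed=int(c))
                 for c in TISSUE_CLASSES]
        cfg = st.TrainConfig(epochs=5)
        m1 = st.train_segmenter(tiles, cfg, seed=42)
        m2 = st.train_segmenter(tiles, cfg, seed=42)
        assert m1.history[-1]["loss"] == pytest.approx(
            m2.history[-1]["loss"], abs=1e-12)
        assert m1.fingerprint == m2.fingerprint

    def test_checkpoint_roundtrip(self, trained_model, tmp_path):
        save_model(trained_model, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        assert back.fingerprint == trained_model.fingerprint


class TestSegmentRaster:
    def test_single_class_tile_is_recovered(self, trained_model):
        t = st.generate_tile({TissueClass.MUSCLE}, 384, 0.455, seed=77)
        seg = st.segment_raster(trained_model, t.image, 0.455)
        tissue = seg.labels != TissueClass.BACKGROUND
        assert (seg.labels[tissue] == TissueClass.MUSCLE).mean() >= 0.99

    def test_pure_white_raster_is_all_background(self, trained_model):
        white = np.full((300, 300, 3), 255, np.uint8)
        seg = st.segment_raster(trained_model, white, 0.455)
        assert (seg.labels == TissueClass.BACKGROUND).all()

    @pytest.mark.parametrize("size", [256, 300, 1000])
    def test_output_shape_matches_input(self, trained_model, size):
        t = st.generate_tile({0, 1}, max(size, 64), 0.455, seed=size)
        img = t.image[:size, :size]
        seg = st.segment_raster(trained_model, img, 0.455)
        assert seg.labels.shape == (size, size)

    def test_nonpositive_spacing_rejected(self, trained_model):
        with pytest.raises(ParameterError):
            st.segment_raster(trained_model,
                              np.zeros((256, 256, 3), np.uint8), 0)

    def test_two_region_map_has_few_isolated_islands(self, trained_model):
        t = st.generate_tile({TissueClass.TUMOR, TissueClass.STROMA}, 512,
                             0.455, seed=21)
        seg = st.segment_raster(trained_model, t.image, 0.455)
        lab = seg.labels
        interior = lab[1:-1, 1:-1]
        isolated = ((interior != lab[:-2, 1:-1]) & (interior != lab[2:, 1:-1])
                    & (interior != lab[1:-1, :-2]) & (interior != lab[1:-1, 2:]))
        assert isolated.mean() <= 0.01


class TestEvaluation:
    def test_perfect_prediction(self, nine_class_tile):
        region = nine_class_tile.mask != TissueClass.BACKGROUND
        m = evaluate_segmentation(nine_class_tile.mask, nine_class_tile.mask,
                                  region)
        assert m.overall_accuracy == 1.0
        present = set(np.unique(nine_class_tile.mask)) - {9}
        for code in present:
            from stromalyzer.classes import CLASS_LEGEND
            assert m.per_class_sensitivity[CLASS_LEGEND[code]] == 1.0

    def test_hand_counted_two_by_two_confusion(self):
        truth = np.array([[0, 0], [1, 1]], np.uint8)      # tumor, stroma
        pred = np.array([[0, 1], [1, 1]], np.uint8)
        m = evaluate_segmentation(pred, truth, np.ones((2, 2), bool))
        assert m.per_class_sensitivity["tumor"] == 0.5
        assert m.per_class_specificity["tumor"] == 1.0
        assert m.per_class_sensitivity["stroma"] == 1.0
        assert m.per_class_specificity["stroma"] == 0.5
        assert m.overall_accuracy == 0.75

    def test_total_disagreement(self):
        truth = np.full((4, 4), int(TissueClass.STROMA), np.uint8)
        pred = np.full((4, 4), int(TissueClass.TUMOR), np.uint8)
        m = evaluate_segmentation(pred, truth, np.ones((4, 4), bool))
        assert m.per_class_sensitivity["stroma"] == 0.0
        assert m.overall_accuracy == 0.0

    def test_truth_count_identity(self, rng):
        truth = rng.integers(0, 9, (30, 30)).astype(np.uint8)
        pred = rng.integers(0, 9, (30, 30)).astype(np.uint8)
        region = rng.random((30, 30)) < 0.7
        m = evaluate_segmentation(pred, truth, region)
        for i in range(9):
            row = m.confusion[i].sum()  # TP + FN for class i
            assert row == np.count_nonzero(truth[region] == i)

    def test_empty_region_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            evaluate_segmentation(np.zeros((4, 4), np.uint8),
                                  np.zeros((4, 4), np.uint8),
                                  np.zeros((4, 4), bool))


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def cv_result(self) -> CrossValResult:
        tiles = {f"slide{i}": [st.generate_tile({int(c)}, 384, 0.455,
                                                seed=i * 16 + int(c))
                               for c in TISSUE_CLASSES]
                 for i in range(10)}
        cfg = st.TrainConfig(epochs=15)
        return st.crossvalidate(tiles, k=5, seed=0, config=cfg)

    def test_folds_partition_slides(self, cv_result):
        folds = {}
        for sid, fi in cv_result.fold_assignment.items():
            folds.setdefault(fi, set()).add(sid)
        assert len(folds) == 5
        assert all(len(s) == 2 for s in folds.values())
        union = set().union(*folds.values())
        assert union == set(cv_result.fold_assignment)

    def test_pooled_accuracy_is_trace_over_sum_of_summed_tables(self, cv_result):
        summed = sum(m.confusion for m in cv_result.per_fold)
        assert cv_result.pooled.overall_accuracy == pytest.approx(
            metrics_from_confusion(summed).overall_accuracy)

    def test_same_seed_same_folds(self, cv_result):
        # re-derive the assignment with an identical shuffle
        slide_ids = sorted(f"slide{i}" for i in range(10))
        order = [slide_ids[i]
                 for i in np.random.default_rng(0).permutation(10)]
        folds = [list(f) for f in np.array_split(np.asarray(order, object), 5)]
        expected = {sid: fi for fi, f in enumerate(folds) for sid in f}
        assert cv_result.fold_assignment == expected

    def test_too_few_slides_rejected(self):
        with pytest.raises(FoldError):
            st.crossvalidate({"a": [], "b": []}, k=5)


def test_background_mask_majority_cleanup():
    img = np.full((9, 9, 3), 250, np.uint8)
    img[4, 4] = 10  # single dark speck inside glass
    bg = tissue_background_mask(img)
    assert bg[4, 4]  # cleaned by the 3x3 majority filter
    assert bg.all()
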