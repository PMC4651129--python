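"""Superpixel segmentation: partitioning, features, training, CV hygiene."""

import numpy as np
import pandas as pd
import pytest

from tmascore.segmentation import (
    SuperpixelMap,
    assign_folds,
    compute_superpixels,
    cross_validate,
    extract_features,
    pixel_agreement,
    predict_mask,
    train_segmenter,
)
from tmascore.synthetic import generate_spot, study_scale_config
from tmascore.types import LabelMask, N, OUTSIDE, SpotImage, T


def uniform_spot(size=200, value=128):
    pixels = np.full((size, size, 3), value, np.uint8)
    c = (size - 1) / 2
    ii, jj = np.mgrid[0:size, 0:size]
    inside = (ii - c) ** 2 + (jj - c) ** 2 <= c**2
    return SpotImage(pixels, 1.0, inside)


class TestComputeSuperpixels:
    def test_uniform_image_full_coverage_and_regular_sizes(self):
        img = uniform_spot()
        spmap = compute_superpixels(img, 16, 10.0)
        inside = img.inside_spot
        assert (spmap.ids[inside] >= 0).all()
        assert (spmap.ids[~inside] == -1).all()
        areas = np.bincount(spmap.ids[inside])
        assert 16**2 / 2 <= areas.mean() <= 16**2 * 2

    def test_each_superpixel_is_connected(self):
        from scipy import ndimage

        img = uniform_spot(120)
        spmap = compute_superpixels(img, 12, 10.0)
        for i in range(spmap.n_superpixels):
            _, n = ndimage.label(spmap.ids == i, structure=np.ones((3, 3), int))
            assert n == 1

    def test_deterministic(self, small_spot):
        _, image, _ = small_spot
        a = compute_superpixels(image, 16, 10.0)
        b = compute_superpixels(image, 16, 10.0)
        assert np.array_equal(a.ids, b.ids)

    def test_boundary_recall_on_synthetic_spot(self, small_spot):
        from scipy import ndimage

        _, image, truth = small_spot
        spmap = compute_superpixels(image, 16)
        t = truth.mask.labels == T
        gt_boundary = t & ~ndimage.binary_erosion(t)
        ids = spmap.ids
        sp_boundary = np.zeros_like(gt_boundary)
        sp_boundary[:, 1:] |= (ids[:, 1:] != ids[:, :-1])
        sp_boundary[1:, :] |= (ids[1:, :] != ids[:-1, :])
        dist_to_sp_boundary = ndimage.distance_transform_edt(~sp_boundary)
        recall = (dist_to_sp_boundary[gt_boundary] <= 2).mean()
        assert recall >= 0.80

    def test_region_size_larger_than_spot_rejected(self):
        with pytest.raises(ValueError):
            compute_superpixels(uniform_spot(40), 50, 10.0)


class TestExtractFeatures:
    def test_constant_image_zero_colour_sd(self):
        img = uniform_spot(80)
        spmap = compute_superpixels(img, 10, 10.0)
        feats = extract_features(img, spmap)
        assert np.allclose(feats["r_sd"], 0)
        assert np.allclose(feats["g_sd"], 0)

    def test_majority_label_and_tie_break(self):
        pixels = np.full((10, 10, 3), 200, np.uint8)
        img = SpotImage(pixels, 1.0, np.ones((10, 10), bool))
        ids = np.zeros((10, 10), int)
        ids[:, 5:] = 1
        labels = np.full((10, 10), N, np.uint8)
        labels[:6, :5] = T  # superpixel 0: 60% T
        labels[:5, 5:] = T  # superpixel 1: exactly 50% T -> tie -> N
        feats = extract_features(img, SuperpixelMap(ids), LabelMask(labels))
        assert feats.loc[0, "label"] == T
        assert feats.loc[1, "label"] == N

    def test_tumour_superpixels_darker_haematoxylin_than_stroma(self, small_spot):
        _, image, truth = small_spot
        spmap = compute_superpixels(image, 16, 10.0)
        feats = extract_features(image, spmap, truth.mask)
        comp = truth.compartments
        stroma_code, tumour_code = 1, 4
        inside = spmap.ids >= 0
        frac_tum = np.bincount(
            spmap.ids[inside], weights=(comp[inside] == tumour_code),
            minlength=spmap.n_superpixels,
        ) / np.bincount(spmap.ids[inside], minlength=spmap.n_superpixels)
        frac_str = np.bincount(
            spmap.ids[inside], weights=(comp[inside] == stroma_code),
            minlength=spmap.n_superpixels,
        ) / np.bincount(spmap.ids[inside], minlength=spmap.n_superpixels)
        tum_mean = feats.loc[frac_tum > 0.9, "haem_od_mean"].mean()
        str_mean = feats.loc[frac_str > 0.9, "haem_od_mean"].mean()
        assert tum_mean > str_mean

    def test_finite_features_with_neighbour_context(self, small_spot):
        _, image, _ = small_spot
        spmap = compute_superpixels(image, 16, 10.0)
        feats = extract_features(image, spmap)
        assert np.isfinite(feats.to_numpy()).all()
        assert any(c.startswith("nb_") for c in feats.columns)


def toy_table(n, label, value, rng):
    return pd.DataFrame(
        {
            "superpixel_id": np.arange(n),
            "x1": rng.normal(value, 0.05, n),
            "x2": rng.normal(-value, 0.05, n),
            "label": label,
        }
    )


class TestTrainSegmenter:
    def test_separable_toy_problem_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        tables = [toy_table(50, T, 1.0, rng), toy_table(50, N, -1.0, rng)]
        model = train_segmenter(tables, "A", seed=1)
        merged = pd.concat(tables, ignore_index=True)
        preds = model.predict_labels(merged)
        assert (preds == merged["label"].to_numpy()).all()

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="N"):
            train_segmenter([toy_table(30, T, 1.0, rng)], "A", seed=0)

    def test_seeded_determinism_of_predictions(self):
        rng = np.random.default_rng(2)
        tables = [toy_table(80, T, 0.3, rng), toy_table(80, N, -0.3, rng)]
        held = toy_table(40, N, 0.0, np.random.default_rng(5))
        p1 = train_segmenter(tables, "A", seed=9).predict_scores(held)
        p2 = train_segmenter(tables, "A", seed=9).predict_scores(held)
        assert np.array_equal(p1, p2)

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        tables = [toy_table(30, T, 1.0, rng), toy_table(30, N, -1.0, rng)]
        model = train_segmenter(tables, "A", seed=0)
        bad = toy_table(10, N, 0.0, rng).rename(columns={"x1": "z1"})
        with pytest.raises(ValueError, match="schema"):
            model.predict_scores(bad)

    def test_model_round_trips_through_file(self, tmp_path):
        from tmascore.segmentation import SegmenterModel

        rng = np.random.default_rng(4)
        tables = [toy_table(30, T, 1.0, rng), toy_table(30, N, -1.0, rng)]
        model = train_segmenter(tables, "B", seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = SegmenterModel.load(path)
        assert loaded.annotator_tag == "B"
        held = toy_table(10, N, 0.0, rng)
        assert np.array_equal(loaded.predict_scores(held), model.predict_scores(held))


class TestFoldAssignment:
    def test_thirty_two_spots_eight_folds(self):
        folds = assign_folds(32, 8, seed=0)
        sizes = np.bincount(folds, minlength=8)
        assert (sizes == 4).all()
        assert set(folds) == set(range(8))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(4, 8, seed=0)

    def test_same_seed_same_assignment(self):
        assert np.array_equal(assign_folds(20, 5, 3), assign_folds(20, 5, 3))


@pytest.fixture(scope="module")
def tiny_cohort():
    spots = []
    for i in range(4):
        cfg = study_scale_config(seed=300 + i, diameter_px=360)
        image, truth = generate_spot(cfg)
        spots.append((image, truth.mask))
    return spots


class TestPredictAndCV:
    def test_cv_predicts_ground_truth_on_separable_spots(self, tiny_cohort):
        report = cross_validate(tiny_cohort, k=2, seed=0, region_size_px=12)
        assert report.mean_pixel_agreement >= 0.90
        for pred, (image, mask) in zip(report.predicted_masks, tiny_cohort):
            assert set(np.unique(pred.labels)) <= {OUTSIDE, N, T}
            assert np.array_equal(pred.labels == OUTSIDE, mask.labels == OUTSIDE)

    def test_each_spot_predicted_once_by_unseen_model(self, tiny_cohort):
        report = cross_validate(tiny_cohort, k=2, seed=1, region_size_px=12)
        assert len(report.predicted_masks) == len(tiny_cohort)
        assert all(m is not None for m in report.predicted_masks)
        assert sorted(report.per_spot["spot"]) == list(range(len(tiny_cohort)))

    def test_blank_spot_predicts_all_n(self, tiny_cohort):
        from tmascore.segmentation import compute_superpixels as _  # noqa: F401

        tables = []
        from tmascore.segmentation import extract_features, compute_superpixels

        for image, mask in tiny_cohort:
            spmap = compute_superpixels(image, 12, 10.0)
            tables.append(extract_features(image, spmap, reference_mask=mask))
        model = train_segmenter(tables, "A", seed=0)
        blank_cfg = study_scale_config(
            seed=900,
            diameter_px=360,
            tumour_fraction=0.0,
            programmed_percent_positive=0.0,
            programmed_intensity_bin=0,
            nucleus_density_per_mm2={
                "tumour": 0.0,
                "normal_epithelium": 0.0,
                "lymphocyte": 0.0,
                "stroma_cell": 0.0,
            },
        )
        blank_img, _truth = generate_spot(blank_cfg)
        pred = predict_mask(blank_img, model, region_size_px=12)
        inside = blank_img.inside_spot
        assert (pred.labels[inside] == N).mean() > 0.99
        assert (pred.labels[~inside] == OUTSIDE).all()
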