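from dataclasses import replace

import numpy as np
import pytest

import seasight as ss
from seasight.calibration import TrainingSet
from seasight.features import DESCRIPTOR_SIZE, extract_descriptors
from seasight.localization import (
    ClassModel,
    classify_region,
    locate,
    track_sequence,
    train_class_model,
)
from seasight.synthetic import SceneSpec, generate_class_patches, generate_scene, generate_sequence


@pytest.fixture(scope="module")
def patches():
    spec = SceneSpec(noise_sigma=0.0, blur_sigma=0.0)
    return {
        c: generate_class_patches(c, 10, spec, seed=21, style="roi")
        for c in ("land", "animal", "sky")
    }


class TestTrainClassModel:
    def test_single_image_prototype_is_its_aggregate(self, patches):
        singles = {c: TrainingSet(c, ts.images[:1]) for c, ts in patches.items()}
        model = train_class_model(singles["land"], singles["animal"], singles["sky"])
        agg = extract_descriptors(patches["animal"].images[0]).aggregate()
        np.testing.assert_allclose(model.prototypes["animal"], agg)
        np.testing.assert_allclose(model.weights["animal"], np.linalg.norm(agg))

    def test_duplicating_images_doubles_weight_not_prototype(self, patches):
        base = {c: TrainingSet(c, ts.images[:3]) for c, ts in patches.items()}
        doubled = {c: TrainingSet(c, ts.images[:3] * 2) for c, ts in patches.items()}
        m1 = train_class_model(base["land"], base["animal"], base["sky"])
        m2 = train_class_model(doubled["land"], doubled["animal"], doubled["sky"])
        for c in ("land", "animal", "sky"):
            np.testing.assert_allclose(m1.prototypes[c], m2.prototypes[c])
            np.testing.assert_allclose(2 * m1.weights[c], m2.weights[c])

    def test_prototypes_mutually_distinct(self, class_model):
        p = class_model.prototypes
        for a, b in (("land", "animal"), ("animal", "sky"), ("land", "sky")):
            assert np.linalg.norm(p[a] - p[b]) > 0

    def test_featureless_class_is_training_failure(self, patches):
        flat = TrainingSet("sky", [np.full((40, 40, 3), 200, dtype=np.uint8)])
        with pytest.raises(ValueError, match="training failure"):
            train_class_model(patches["land"], patches["animal"], flat)

    def test_model_json_roundtrip(self, class_model, tmp_path):
        path = tmp_path / "model.json"
        class_model.save(path)
        loaded = ClassModel.load(path)
        for c in ("land", "animal", "sky"):
            np.testing.assert_allclose(loaded.prototypes[c], class_model.prototypes[c])
            assert loaded.weights[c] == pytest.approx(class_model.weights[c])


class TestClassifyRegion:
    def test_zero_distance_to_own_single_image_class(self, patches):
        singles = {c: TrainingSet(c, ts.images[:1]) for c, ts in patches.items()}
        model = train_class_model(singles["land"], singles["animal"], singles["sky"])
        res = classify_region(patches["animal"].images[0], model)
        assert res.distances["animal"] == pytest.approx(0.0, abs=1e-18)
        assert res.decision == "animal"

    def test_all_tied_resolves_to_animal(self, patches):
        proto = extract_descriptors(patches["animal"].images[0]).aggregate()
        model = ClassModel(
            {c: proto for c in ("land", "animal", "sky")},
            {c: 1.0 for c in ("land", "animal", "sky")},
            {},
        )
        res = classify_region(patches["land"].images[0], model)
        assert res.decision == "animal"

    def test_empty_region_gives_no_decision(self, class_model):
        res = classify_region(np.zeros((40, 40, 3), dtype=np.uint8), class_model)
        assert res.decision is None and not res.located

    def test_distances_nonnegative_scores_normalized(self, patches, class_model):
        res = classify_region(patches["sky"].images[0], class_model)
        assert all(m >= 0 for m in res.distances.values())
        assert sum(res.scores.values()) == pytest.approx(1.0)

    def test_deterministic(self, patches, class_model):
        img = patches["animal"].images[1]
        r1 = classify_region(img, class_model)
        r2 = classify_region(img, class_model)
        assert r1.decision == r2.decision and r1.scores == r2.scores

    def test_literal_min_distance_mode(self, patches, class_model):
        res = classify_region(patches["animal"].images[2], class_model, decision_mode="distance")
        assert res.decision in ("land", "animal", "sky")

    def test_animal_rois_classified_as_animal(self, patches, class_model):
        test = generate_class_patches(
            "animal", 10, SceneSpec(noise_sigma=0.0, blur_sigma=0.0), seed=77, style="roi"
        )
        hits = sum(classify_region(im, class_model).decision == "animal" for im in test.images)
        assert hits >= 9

    def test_scale_doubling_rarely_flips_decision(self, class_model):
        from skimage.transform import resize

        test = generate_class_patches(
            "animal", 10, SceneSpec(noise_sigma=0.0, blur_sigma=0.0), seed=88, style="roi"
        )
        flips = 0
        for im in test.images:
            r1 = classify_region(im, class_model)
            big = resize(im.astype(float), (2 * im.shape[0], 2 * im.shape[1], 3), order=1, anti_aliasing=True)
            flips += classify_region(big, class_model).decision != r1.decision
        assert flips < 0.1 * len(test.images) + 1e-9 or flips <= 0  # < 10% of trials


class TestLocate:
    def test_centroid_within_5px_of_truth(self, noise_free_spec, calibrated_thresholds, class_model):
        img, gt = generate_scene(replace(noise_free_spec, seed=101))
        res = locate(img, *calibrated_thresholds, class_model)
        assert res.located
        err = np.hypot(res.centroid[0] - gt.centroid[0], res.centroid[1] - gt.centroid[1])
        assert err <= 5.0
        t, l, b, r = res.bbox
        assert 0 <= l < r <= img.shape[1] and 0 <= t < b <= img.shape[0]

    def test_scene_without_animal_gives_absent_location(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        img, _ = generate_scene(replace(noise_free_spec, animal=False, seed=55))
        res = locate(img, *calibrated_thresholds, class_model)
        assert not res.located and res.centroid is None

    def test_bird_distractors_do_not_yield_a_location(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        img, _ = generate_scene(
            replace(noise_free_spec, animal=False, n_distractors=3, seed=56)
        )
        res = locate(img, *calibrated_thresholds, class_model)
        assert not res.located and res.decision != "animal"

    def test_single_index_pipelines_also_work(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        img, gt = generate_scene(replace(noise_free_spec, seed=102))
        thr_ngmr, thr_nbmg = calibrated_thresholds
        for args in ((thr_ngmr, None), (None, thr_nbmg)):
            res = locate(img, *args, class_model)
            assert res.located
            assert np.hypot(res.centroid[0] - gt.centroid[0], res.centroid[1] - gt.centroid[1]) <= 5

    def test_requires_some_thresholds(self, class_model, noise_free_spec):
        img, _ = generate_scene(noise_free_spec)
        with pytest.raises(ValueError):
            locate(img, None, None, class_model)


class TestTrackSequence:
    def test_identical_frames_identical_coordinates(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        img, _ = generate_scene(replace(noise_free_spec, seed=103))
        out = track_sequence([img, img, img], *calibrated_thresholds, class_model)
        assert out[0][1:] == out[1][1:] == out[2][1:]

    def test_equals_map_of_locate(self, noise_free_spec, calibrated_thresholds, class_model):
        """No hidden state: track_sequence(frames) == map(locate, frames)."""
        frames, _ = generate_sequence(
            replace(noise_free_spec, seed=104), 3, [(60, 122), (100, 122), (140, 122)]
        )
        out = track_sequence(frames, *calibrated_thresholds, class_model)
        for (i, x, y), frame in zip(out, frames):
            res = locate(frame, *calibrated_thresholds, class_model)
            assert (x, y) == (res.centroid if res.located else (None, None))

    def test_linear_trajectory_tracked_within_5px(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        traj = [(40.0 + 15 * i, 122.0) for i in range(8)]
        frames, track = generate_sequence(replace(noise_free_spec, seed=105), 8, traj)
        out = track_sequence(frames, *calibrated_thresholds, class_model)
        for (i, x, y), (gx, gy) in zip(out, track):
            assert x is not None
            assert np.hypot(x - gx, y - gy) <= 5.0

    def test_animal_free_frame_absent_only_there(
        self, noise_free_spec, calibrated_thresholds, class_model
    ):
        frames, _ = generate_sequence(
            replace(noise_free_spec, seed=106), 2, [(60, 122), (140, 122)]
        )
        gap, _ = generate_scene(replace(noise_free_spec, animal=False, seed=107))
        out = track_sequence([frames[0], gap, frames[1]], *calibrated_thresholds, class_model)
        assert out[0][1] is not None and out[2][1] is not None
        assert out[1][1:] == (None, None)

    def test_empty_sequence_rejected(self, calibrated_thresholds, class_model):
        with pytest.raises(ValueError):
            track_sequence([], *calibrated_thresholds, class_model)


def test_annotate_image_draws_red_box(noise_free_spec, calibrated_thresholds, class_model):
    img, _ = generate_scene(replace(noise_free_spec, seed=108))
    res = locate(img, *calibrated_thresholds, class_model)
    boxed = ss.localization.annotate_image(img, res, style="box")
    t, l, b, r = res.bbox
    assert tuple(boxed[t, l]) == (255, 0, 0)
    crossed = ss.localization.annotate_image(img, res, style="cross")
    x, y = int(round(res.centroid[0])), int(round(res.centroid[1]))
    assert tuple(crossed[y, x]) == (255, 0, 0)
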