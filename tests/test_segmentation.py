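"""Patching, both segmentation backends, training and F1 evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizolapse.segmentation import (
    ModelStateError,
    SegmentationModel,
    _downsample,
    _upsample_nearest,
    extract_patches,
    f1_score,
    load_model,
    save_model,
    segment,
    stitch_patches,
    train,
)


class TestPatching:
    def test_patch_count_for_plate_sized_frame(self):
        # 4639 x 4480 at 256 px patches: 19 * 18 = 342 tiles
        img = np.zeros((4639, 4480), np.uint8)
        grid, patches = extract_patches(img, 256)
        assert len(patches) == 342
        assert stitch_patches(grid, patches).shape == (4639, 4480)

    def test_single_patch_image(self):
        img = np.arange(256 * 256, dtype=np.uint8).reshape(256, 256)
        grid, patches = extract_patches(img, 256)
        assert len(patches) == 1
        assert grid.offsets == [(0, 0)]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        h=st.integers(1, 300),
        w=st.integers(1, 300),
        ps=st.integers(8, 64),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_is_identity_for_any_dims(self, h, w, ps, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
        grid, patches = extract_patches(img, ps)
        assert np.array_equal(stitch_patches(grid, patches), img)

    def test_stitch_counts_disjoint_single_hot_patches(self):
        img = np.zeros((100, 70), np.uint8)
        grid, patches = extract_patches(img, 32)
        hot = np.zeros_like(patches)
        for k in range(len(hot)):
            hot[k, k % 32, (k * 7) % 32] = 1
        out = stitch_patches(grid, hot)
        # only hot pixels landing inside the unpadded area survive
        expected = 0
        for k, (y, x) in enumerate(grid.offsets):
            if y + k % 32 < 100 and x + (k * 7) % 32 < 70:
                expected += 1
        assert out.sum() == expected

    def test_stitch_patch_count_mismatch_raises(self):
        img = np.zeros((64, 64), np.uint8)
        grid, patches = extract_patches(img, 32)
        with pytest.raises(ValueError, match="expected"):
            stitch_patches(grid, patches[:-1])

    def test_seed_path_downsample_idempotent_on_blocky_masks(self, rng):
        blocky = _upsample_nearest(
            (rng.uniform(size=(32, 32)) > 0.5).astype(np.uint8), 8
        )
        down_up = _upsample_nearest(
            (_downsample(blocky, 8) > 0.5).astype(np.uint8), 8
        )
        assert np.array_equal(blocky, down_up)


class TestClassicalBackend:
    def test_blank_frame_gives_empty_mask(self):
        model = SegmentationModel(backend="classical")
        blank = np.full((120, 90), 30, np.uint8)
        assert segment(blank, model).sum() == 0

    def test_noiseless_frame_recovers_truth(self, noiseless_plate):
        _, series, _, masks = noiseless_plate
        model = SegmentationModel(backend="classical")
        pred = segment(series.frames[-1], model)
        assert f1_score(pred, masks[-1]).f1 >= 0.95

    def test_mask_is_binary(self, small_plate):
        _, series, _, _ = small_plate
        model = SegmentationModel(backend="classical")
        mask = segment(series.frames[-1], model)
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.shape == series.frames[-1].shape


class TestLearnedBackend:
    def test_training_is_deterministic(self, small_plate):
        _, series, _, masks = small_plate
        imgs, labs = list(series.frames[:8]), list(masks[:8])
        params = {"epochs": 10, "rng_seed": 5}
        m1 = train(imgs, labs, "root", params)
        m2 = train(imgs, labs, "root", params)
        assert m1.weights_hash() == m2.weights_hash()

    def test_separable_data_reaches_high_f1(self, small_plate):
        _, series, _, masks = small_plate
        model = train(
            list(series.frames[:8]),
            list(masks[:8]),
            "root",
            {"epochs": 10, "rng_seed": 5},
        )
        held = f1_score(segment(series.frames[9], model), masks[9])
        assert held.f1 >= 0.99

    def test_loss_trend_non_increasing_on_average(self, small_plate):
        _, series, _, masks = small_plate
        model = train(
            list(series.frames[:8]),
            list(masks[:8]),
            "root",
            {"epochs": 10, "rng_seed": 5},
        )
        losses = np.asarray(model.losses_)
        assert len(losses) == 10
        # averaged over halves, training does not diverge
        assert losses[5:].mean() <= losses[:5].mean() + 1e-6

    def test_backends_agree_on_synthetic_frames(self, small_plate):
        _, series, _, masks = small_plate
        learned = train(
            list(series.frames[:8]),
            list(masks[:8]),
            "root",
            {"epochs": 10, "rng_seed": 5},
        )
        classical = SegmentationModel(backend="classical")
        a = segment(series.frames[9], learned)
        b = segment(series.frames[9], classical)
        assert f1_score(a, b).f1 >= 0.95

    def test_untrained_model_raises_model_state_error(self):
        model = SegmentationModel(backend="learned")
        with pytest.raises(ModelStateError):
            segment(np.zeros((32, 32), np.uint8), model)

    def test_empty_label_set_raises(self):
        with pytest.raises(ValueError):
            train([], [], "root")

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimensions"):
            train(
                [np.zeros((32, 32), np.uint8)],
                [np.zeros((16, 16), np.uint8)],
                "root",
            )

    def test_model_roundtrips_through_checkpoint(self, small_plate, tmp_path):
        _, series, _, masks = small_plate
        model = train(
            list(series.frames[:4]),
            list(masks[:4]),
            "root",
            {"epochs": 3, "rng_seed": 5},
        )
        path = save_model(model, tmp_path / "root.joblib")
        back = load_model(path)
        assert back.weights_hash() == model.weights_hash()
        assert back.target == "root"
        assert np.array_equal(
            segment(series.frames[4], back), segment(series.frames[4], model)
        )


class TestF1Score:
    def test_perfect_prediction(self):
        truth = np.zeros((20, 20), bool)
        truth[5:10, 5:10] = True
        s = f1_score(truth, truth)
        assert (s.precision, s.sensitivity, s.f1) == (1.0, 1.0, 1.0)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2], b[5:] = True, True
        assert f1_score(a, b).f1 == 0.0

    def test_harmonic_mean_hand_value(self):
        # precision 0.8, sensitivity 0.75 -> F1 = 2*0.6/1.55
        truth = np.zeros(400, bool)
        pred = np.zeros(400, bool)
        truth[:80] = True  # 80 positives
        pred[20:95] = True  # 75 predicted, 60 true positives
        s = f1_score(pred.reshape(20, 20), truth.reshape(20, 20))
        assert s.precision == pytest.approx(0.8)
        assert s.sensitivity == pytest.approx(0.75)
        assert s.f1 == pytest.approx(0.774194, abs=1e-6)

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError):
            f1_score(np.zeros((3, 3)), np.zeros((4, 4)))
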