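"""Segmenter contracts: probability maps, augmentation, training, CV folds."""

import dataclasses

import numpy as np
import pytest

from muscleidp.segmenter import (
    AugmentationSpec,
    ResUNet,
    SegmenterConfig,
    Study,
    TrainConfig,
    augment_pair,
    build_segmenter,
    crossvalidate,
    mean_foreground_dice,
    train,
)


def _toy_studies(n_studies, n_slices=2, size=16, seed=0):
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_studies):
        imgs = rng.random((n_slices, size, size)).astype(np.float32)
        labs = np.zeros((n_slices, size, size), dtype=np.int16)
        labs[:, 4:10, 4:10] = 1  # a square "muscle"
        studies.append(Study(f"st{i}", imgs, labs))
    return studies


class TestBuildSegmenter:
    def test_probability_channels_sum_to_one(self, rng):
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=0)
        p = model.predict_proba(rng.random((3, 16, 16)))
        assert p.shape == (3, 13, 16, 16)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_more_residual_units_means_more_parameters(self):
        counts = {
            n: build_segmenter(SegmenterConfig(residual_units=n), seed=0).n_parameters()
            for n in (1, 2, 3, 4)
        }
        assert counts[4] > counts[3] > counts[2] > counts[1]

    def test_same_config_and_seed_builds_identical_models(self, rng):
        x = rng.random((1, 16, 16))
        a = build_segmenter(SegmenterConfig(residual_units=2, base_channel_width=4), seed=5)
        b = build_segmenter(SegmenterConfig(residual_units=2, base_channel_width=4), seed=5)
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_indivisible_slice_size_rejected_naming_factor(self):
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=0)
        with pytest.raises(ValueError, match="multiples of 8"):
            model.predict_proba(np.zeros((20, 20)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SegmenterConfig(residual_units=5)
        with pytest.raises(ValueError):
            SegmenterConfig(out_channels=12)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=2)
        x = rng.random((1, 16, 16))
        before = model.predict_proba(x)
        path = tmp_path / "m.npz"
        model.save(path)
        other = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=99)
        other.load(path)
        np.testing.assert_array_equal(other.predict_proba(x), before)


class TestAugmentation:
    def test_zero_width_ranges_are_identity(self, rng):
        spec = AugmentationSpec(zoom_range=(0, 0), rotation_range_deg=(0, 0), apply_probability=1.0)
        img = rng.random((16, 16)).astype(np.float32)
        lab = (img > 0.5).astype(np.int16)
        img2, lab2 = augment_pair(img, lab, spec, rng)
        np.testing.assert_allclose(img2, img, atol=1e-6)
        np.testing.assert_array_equal(lab2, lab)

    def test_label_palette_preserved(self, rng):
        spec = AugmentationSpec(apply_probability=1.0)
        lab = rng.integers(0, 13, (32, 32)).astype(np.int16)
        img = rng.random((32, 32)).astype(np.float32)
        for _ in range(10):
            _, lab2 = augment_pair(img, lab, spec, rng)
            assert set(np.unique(lab2)) <= set(np.unique(lab))

    def test_rotation_preserves_disk_area_within_5pct(self, rng):
        yy, xx = np.mgrid[:64, :64]
        disk = (((yy - 31.5) ** 2 + (xx - 31.5) ** 2) <= 15**2).astype(np.int16)
        spec = AugmentationSpec(zoom_range=(0, 0), apply_probability=1.0)
        for _ in range(10):
            _, lab2 = augment_pair(disk.astype(np.float32), disk, spec, rng)
            assert abs(int(lab2.sum()) - int(disk.sum())) / disk.sum() < 0.05

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 5)), AugmentationSpec(), rng)


class TestTrain:
    def test_one_epoch_smoke_run_yields_finite_loss(self):
        studies = _toy_studies(3)
        cfg = TrainConfig(lr_schedule=((1, 1e-3),), augmentation=None, batch_size=2, seed=0)
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=0)
        model, hist = train(model, studies[:2], studies[2:], cfg)
        assert np.isfinite(hist["train_loss"][0])
        assert len(hist["val_dice"]) == 1

    def test_loss_descends_after_ten_steps_on_same_batch(self):
        """Ten optimization steps on one fixed batch reduce its loss."""
        from muscleidp._nn import Adam
        from muscleidp.segmenter import _one_hot, soft_dice_loss

        rng = np.random.default_rng(4)
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=4)
        x = rng.random((4, 16, 16, 1)).astype(np.float32)
        y = np.zeros((4, 16, 16), dtype=np.int16)
        y[:, 4:12, 4:12] = 3
        oh = _one_hot(y, 13)
        opt = Adam(model.params(), lr=1e-3)
        loss0, gz = soft_dice_loss(model.forward_logits(x, True), oh)
        for _ in range(10):
            z = model.forward_logits(x, True)
            loss, gz = soft_dice_loss(z, oh)
            opt.zero_grad()
            model.backward(gz)
            opt.step()
        loss10, _ = soft_dice_loss(model.forward_logits(x, True), oh)
        assert loss10 < loss0

    def test_study_overlap_between_splits_is_data_leakage_error(self):
        studies = _toy_studies(3)
        cfg = TrainConfig(lr_schedule=((1, 1e-3),), seed=0)
        model = build_segmenter(SegmenterConfig(residual_units=1, base_channel_width=4), seed=0)
        with pytest.raises(ValueError, match="leakage"):
            train(model, studies[:2], studies[1:], cfg)

    def test_training_is_reproducible_under_seed(self):
        studies = _toy_studies(4)
        cfg = TrainConfig(lr_schedule=((2, 1e-3),), batch_size=2, seed=11)
        hists = []
        for _ in range(2):
            model = build_segmenter(
                SegmenterConfig(residual_units=1, base_channel_width=4), seed=11
            )
            _, h = train(model, studies[:3], studies[3:], cfg)
            hists.append(h)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_dice"] == hists[1]["val_dice"]


class TestCrossValidate:
    def test_95_studies_give_19_per_fold(self):
        studies = _toy_studies(95, n_slices=1, size=8)
        res = crossvalidate(
            studies,
            k=5,
            repeats=1,
            seed=0,
            train_fn=lambda tr, va, s: (lambda imgs: np.zeros_like(imgs, dtype=np.int16)),
        )
        for fold in res["folds"][0]:
            assert len(fold) == 19

    def test_folds_partition_the_study_set(self):
        studies = _toy_studies(13)
        res = crossvalidate(
            studies,
            k=5,
            repeats=2,
            seed=3,
            train_fn=lambda tr, va, s: (lambda imgs: np.zeros_like(imgs, dtype=np.int16)),
        )
        for rep in res["folds"]:
            all_idx = sorted(i for fold in rep for i in fold)
            assert all_idx == list(range(13))
            for a in range(5):
                for b in range(a + 1, 5):
                    assert not (set(rep[a]) & set(rep[b]))

    def test_aggregate_sd_matches_brute_force_over_fold_means(self):
        """With a fixed 'predictor', the aggregate SD equals the SD of fold
        means recomputed by an explicit loop over the fold assignments."""
        studies = _toy_studies(10, n_slices=2, size=16, seed=5)

        def predictor(imgs):
            # deterministic rule: everything above median is class 1
            out = np.zeros(imgs.shape, dtype=np.int16)
            out[:, 4:9, 4:9] = 1
            return out

        res = crossvalidate(
            studies, k=5, repeats=1, seed=7, train_fn=lambda tr, va, s: predictor
        )
        fold_means = []
        for fold in res["folds"][0]:
            vals = []
            for i in fold:
                pred = predictor(studies[i].images)
                for p, t in zip(pred, studies[i].labels):
                    vals.append(mean_foreground_dice(p, t))
            fold_means.append(np.mean(vals))
        np.testing.assert_allclose(res["fold_dice"][0], fold_means, rtol=1e-12)
        assert res["repeat_sd"][0] == pytest.approx(np.std(fold_means, ddof=1))

    def test_more_folds_than_studies_rejected(self):
        with pytest.raises(ValueError, match="folds exceed"):
            crossvalidate(_toy_studies(3), k=5, repeats=1)
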