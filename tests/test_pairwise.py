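"""Pairwise flow estimation: classical pyramid, losses, learned model."""

import numpy as np
import pytest
from scipy import ndimage

from emflowreg.flow import FlowField, RigidTransform, warp_image
from emflowreg.metrics import endpoint_error, ncc
from emflowreg.pairwise import (
    AugmentationSample,
    ClassicalFlowEstimator,
    LossWeights,
    PWCLiteModel,
    PyramidConfig,
    augmentation_loss,
    charbonnier,
    estimate_flow_classical,
    estimate_flow_learned,
    sample_augmentation,
    smoothness_loss,
    train_unsupervised,
)
from emflowreg.synthetic import TPSDeformSpec, make_registration_pairs, make_textured_image


class TestClassicalEstimator:
    def test_identical_images_near_zero_flow(self, textured_image):
        F = estimate_flow_classical(textured_image, textured_image)
        assert F.magnitude().mean() <= 0.1

    def test_constant_shift_recovery(self):
        ref = make_textured_image((128, 128), seed=21)
        mov = ndimage.shift(ref, (-3.0, 2.0), order=1, mode="nearest")
        F = estimate_flow_classical(mov, ref)
        inner = (slice(16, -16), slice(16, -16))
        epe = np.hypot(F.dy[inner] - (-3.0), F.dx[inner] - 2.0).mean()
        assert epe <= 0.5

    def test_tps_recovery_within_twenty_percent(self):
        mov, ref, gt = make_registration_pairs(
            1, TPSDeformSpec(6, 4.0, seed=2), seed=2, shape=(128, 128)
        )[0]
        F = estimate_flow_classical(mov, ref)
        assert endpoint_error(F, gt) <= 0.2 * np.hypot(gt.dy, gt.dx).mean()

    def test_too_small_for_octaves_raises(self):
        cfg = PyramidConfig(octaves=6)
        with pytest.raises(ValueError):
            estimate_flow_classical(np.zeros((32, 32)), np.zeros((32, 32)), config=cfg)

    def test_for_shape_respects_min_side(self):
        cfg = PyramidConfig.for_shape((64, 64))
        assert cfg.octaves == 3  # 64 -> 32 -> 16


class TestSmoothnessLoss:
    def test_constant_flow_is_zero(self):
        assert smoothness_loss(FlowField.constant((10, 10), 2.0, -1.0)) == 0.0

    def test_unit_ramp_closed_form(self):
        xx = np.tile(np.arange(8.0), (8, 1))
        f = FlowField(np.zeros((8, 8)), xx)
        # dx differences: 1 along columns (8*7 terms); all other diffs 0
        rho1 = float(charbonnier(np.array(1.0)))
        n_total = 2 * (7 * 8 + 8 * 7)
        expected = (8 * 7) * rho1 / n_total
        assert smoothness_loss(f) == pytest.approx(expected, rel=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        f = FlowField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
        total, count = 0.0, 0
        for plane in (f.dy, f.dx):
            for r in range(6):
                for c in range(6):
                    if r + 1 < 6:
                        d = plane[r + 1, c] - plane[r, c]
                        total += np.sqrt(d * d + 1e-6) - 1e-3
                        count += 1
                    if c + 1 < 6:
                        d = plane[r, c + 1] - plane[r, c]
                        total += np.sqrt(d * d + 1e-6) - 1e-3
                        count += 1
        assert smoothness_loss(f) == pytest.approx(total / count, rel=1e-10)


class TestAugmentationLoss:
    def test_identity_augmentation_is_zero(self, textured_image):
        est = ClassicalFlowEstimator()
        aug = AugmentationSample(RigidTransform())
        mov = ndimage.shift(textured_image, (-1.0, 0.5), order=1, mode="nearest")
        assert augmentation_loss(est, mov, textured_image, aug) == pytest.approx(0.0, abs=1e-9)

    def test_finite_on_random_augmentation(self, textured_image, rng):
        est = ClassicalFlowEstimator()
        aug = sample_augmentation(rng)
        mov = ndimage.shift(textured_image, (1.0, -1.0), order=1, mode="nearest")
        val = augmentation_loss(est, mov, textured_image, aug)
        assert np.isfinite(val) and val >= 0


class TestLearnedModel:
    def test_output_shape_for_awkward_input(self):
        model = PWCLiteModel()
        rng = np.random.default_rng(0)
        mov = rng.random((97, 130))
        ref = np.roll(mov, 2, axis=0)
        F = estimate_flow_learned(mov, ref, model)
        assert F.shape == (97, 130)

    def test_inference_deterministic(self, textured_image):
        model = PWCLiteModel()
        mov = np.roll(textured_image, 1, axis=1)
        F1 = model.estimate(mov, textured_image)
        F2 = model.estimate(mov, textured_image)
        assert np.array_equal(F1.dy, F2.dy) and np.array_equal(F1.dx, F2.dx)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = PWCLiteModel()
        model.params = model.params + 0.1
        model.save(tmp_path / "ckpt.npz")
        back = PWCLiteModel.load(tmp_path / "ckpt.npz")
        assert np.array_equal(back.params, model.params)
        assert back.n_levels == model.n_levels


@pytest.fixture(scope="module")
def tiny_pairs():
    return [
        (m, r)
        for m, r, _ in make_registration_pairs(
            6, TPSDeformSpec(5, 3.0, seed=8), seed=8, shape=(48, 48)
        )
    ]


class TestTraining:
    def test_photometric_only_history(self, tiny_pairs):
        _, hist = train_unsupervised(
            tiny_pairs,
            weights=LossWeights(lambda_smooth=0.0, lambda_aug=0.0),
            epochs=2,
            seed=0,
        )
        assert set(hist[0]) == {"ph", "total"}
        assert hist[0]["total"] == pytest.approx(hist[0]["ph"])

    def test_seeded_reproducibility(self, tiny_pairs):
        _, h1 = train_unsupervised(tiny_pairs, epochs=3, seed=7)
        _, h2 = train_unsupervised(tiny_pairs, epochs=3, seed=7)
        assert h1 == h2

    def test_loss_decreases_in_short_run(self, tiny_pairs):
        _, hist = train_unsupervised(
            tiny_pairs,
            weights=LossWeights(lambda_smooth=5.0, lambda_aug=0.0),
            epochs=12,
            seed=1,
        )
        assert hist[-1]["total"] < hist[0]["total"]

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_unsupervised([], epochs=1, seed=0)
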