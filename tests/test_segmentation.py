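"""Atrous convolution oracle, ACNN architecture, training and ROI tools."""

import numpy as np
import pytest

from dermocad import segmentation as seg
from dermocad import synthetic
from dermocad.netspec import receptive_field
from dermocad.suites import _atrous_bruteforce


class TestAtrousConv2d:
    def test_rate_one_equals_standard_convolution(self, rng):
        from scipy import ndimage
        fm = rng.normal(size=(16, 16, 1))
        k = rng.normal(size=(3, 3, 1, 1))
        spec = seg.AtrousConvSpec(3, 3, 1, 1, dilation_rate=1)
        got = seg.atrous_conv2d(fm, spec, k)[:, :, 0]
        want = ndimage.correlate(fm[:, :, 0], k[:, :, 0, 0], mode="constant")
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_impulse_response_lands_on_dilated_offsets(self):
        fm = np.zeros((11, 11, 1))
        fm[5, 5, 0] = 1.0
        k = np.ones((3, 3, 1, 1))
        spec = seg.AtrousConvSpec(3, 3, 1, 1, dilation_rate=2)
        out = seg.atrous_conv2d(fm, spec, k)[:, :, 0]
        nz = set(map(tuple, np.argwhere(out != 0)))
        assert nz == {(5 + dr, 5 + dc) for dr in (-2, 0, 2) for dc in (-2, 0, 2)}

    def test_interior_all_ones_sums_nine_taps(self):
        fm = np.ones((9, 9, 1))
        k = np.ones((3, 3, 1, 1))
        spec = seg.AtrousConvSpec(3, 3, 1, 1, dilation_rate=2)
        out = seg.atrous_conv2d(fm, spec, k)[:, :, 0]
        assert out[4, 4] == 9

    @pytest.mark.parametrize("rate", [1, 2, 4, 8])
    def test_matches_triple_loop_oracle(self, rate, rng):
        fm = rng.normal(size=(12, 14, 2))
        k = rng.normal(size=(3, 3, 2, 3))
        spec = seg.AtrousConvSpec(3, 3, 2, 3, dilation_rate=rate)
        got = seg.atrous_conv2d(fm, spec, k)
        want = _atrous_bruteforce(fm, k, rate)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_zero_inflated_kernel_equivalence(self, rng):
        """Rate-r atrous conv equals standard conv with (r-1) zeros between taps."""
        from scipy import ndimage
        fm = rng.normal(size=(17, 17, 1))
        k = rng.normal(size=(3, 3, 1, 1))
        r = 3
        inflated = np.zeros((2 * r + 1, 2 * r + 1))
        inflated[::r, ::r] = k[:, :, 0, 0]
        spec = seg.AtrousConvSpec(3, 3, 1, 1, dilation_rate=r)
        got = seg.atrous_conv2d(fm, spec, k)[:, :, 0]
        want = ndimage.correlate(fm[:, :, 0], inflated, mode="constant")
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        spec = seg.AtrousConvSpec(3, 3, 2, 1, dilation_rate=1)
        with pytest.raises(ValueError, match="channel mismatch"):
            seg.atrous_conv2d(rng.normal(size=(8, 8, 3)), spec,
                              rng.normal(size=(3, 3, 2, 1)))


class TestBuildAcnn:
    def test_sixteen_feature_layers_in_five_blocks(self):
        model = seg.build_acnn(seed=0)
        spec = model.to_network_spec()
        convs = [l for l in spec.convs() if l.name != "head"]
        assert len(convs) == 16
        blocks = {l.name.split(".")[0] for l in convs}
        assert len(blocks) == 5

    def test_output_resolution_equals_input(self, rng):
        small = seg.ACNNSpec(input_shape=(24, 32, 3), channels=(4, 4, 4, 4, 4))
        model = seg.build_acnn(small, seed=0)
        x = rng.random((1, 3, 24, 32)).astype(np.float32)
        assert model.forward(x, train=False).shape == (1, 2, 24, 32)

    def test_dilation_enlarges_receptive_field(self):
        base = seg.ACNNSpec()
        flat = seg.ACNNSpec(dilation_schedule=(1, 1, 1, 1, 1))
        rf_dilated = receptive_field(seg.build_acnn(base, 0).to_network_spec())[-1]
        rf_flat = receptive_field(seg.build_acnn(flat, 0).to_network_spec())[-1]
        assert rf_dilated > rf_flat

    def test_schedule_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one rate per block"):
            seg.ACNNSpec(dilation_schedule=(1, 2, 4))


@pytest.fixture(scope="module")
def tiny_data():
    rng = np.random.default_rng(12)
    imgs, masks = [], []
    for i in range(6):
        spec = synthetic.random_lesion_spec(
            rng, "MEL" if i % 2 else "BEN", (24, 32))
        img, mask, _ = synthetic.generate_lesion_image(spec)
        imgs.append(img)
        masks.append(mask.astype(np.uint8))
    return imgs, masks


@pytest.fixture(scope="module")
def tiny_spec():
    return seg.ACNNSpec(input_shape=(24, 32, 3), channels=(4, 6, 6, 8, 8))


class TestTrainAcnn:
    def test_loss_decreases(self, tiny_data, tiny_spec):
        imgs, masks = tiny_data
        model = seg.build_acnn(tiny_spec, seed=0)
        cfg = seg.ACNNTrainConfig(epochs=4, batch_size=2)
        history = seg.train_acnn(model, imgs, masks, cfg, seed=0)
        assert history[-1] < history[0]

    def test_zero_learning_rate_leaves_weights(self, tiny_data, tiny_spec):
        imgs, masks = tiny_data
        model = seg.build_acnn(tiny_spec, seed=0)
        before = [p.value.copy() for p in model.params()]
        cfg = seg.ACNNTrainConfig(epochs=1, batch_size=2, learning_rate=0.0, l2=0.0)
        seg.train_acnn(model, imgs, masks, cfg, seed=0)
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_inverse_frequency_weights_ratio(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[:1, :] = 1  # 10 lesion / 90 background pixels
        w = seg.inverse_frequency_weights([m])
        assert w[1] / w[0] == pytest.approx(9.0)

    def test_invalid_mask_values_rejected(self, tiny_data, tiny_spec):
        imgs, _ = tiny_data
        model = seg.build_acnn(tiny_spec, seed=0)
        bad = [np.full(im.shape[:2], 3, dtype=np.uint8) for im in imgs]
        with pytest.raises(ValueError, match="mask values"):
            seg.train_acnn(model, imgs, bad, seg.ACNNTrainConfig(epochs=1), seed=0)

    def test_segment_returns_binary_deterministic_mask(self, tiny_data, tiny_spec):
        imgs, masks = tiny_data
        model = seg.build_acnn(tiny_spec, seed=0)
        seg.train_acnn(model, imgs, masks,
                       seg.ACNNTrainConfig(epochs=2, batch_size=2), seed=0)
        m1 = seg.segment(model, imgs[0])
        m2 = seg.segment(model, imgs[0])
        assert m1.dtype == bool and m1.shape == imgs[0].shape[:2]
        np.testing.assert_array_equal(m1, m2)


class TestCropRoi:
    def test_full_frame_mask_returns_input(self, smooth_lesion):
        img, _, _ = smooth_lesion
        full = np.ones(img.shape[:2], dtype=bool)
        np.testing.assert_array_equal(seg.crop_roi(img, full), img)

    def test_box_arithmetic_with_margin(self):
        img = np.full((40, 40, 3), 9, dtype=np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 15:25] = True
        out = seg.crop_roi(img, mask, margin=2)
        assert out.shape == (14, 14, 3)

    def test_crop_is_shift_equivariant(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(40, 40, 3)).astype(np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:18, 12:20] = True
        shifted_img = np.roll(img, (5, 3), axis=(0, 1))
        shifted_mask = np.roll(mask, (5, 3), axis=(0, 1))
        np.testing.assert_array_equal(
            seg.crop_roi(shifted_img, shifted_mask, margin=1),
            seg.crop_roi(img, mask, margin=1))

    def test_empty_mask_warns_and_returns_full_image(self, smooth_lesion):
        img, _, _ = smooth_lesion
        with pytest.warns(RuntimeWarning, match="empty mask"):
            out = seg.crop_roi(img, np.zeros(img.shape[:2], dtype=bool))
        np.testing.assert_array_equal(out, img)


class TestDice:
    def test_dice_identities(self):
        a = np.zeros((5, 5), dtype=bool)
        a[1:3, 1:3] = True
        assert seg.dice_coefficient(a, a) == 1.0
        assert seg.dice_coefficient(a, ~a) == 0.0
        assert seg.dice_coefficient(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0
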