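"""Autodiff engine, U-Net mechanics, training-pair construction, and
count-level matching."""

import numpy as np
import pytest

from dynapet.denoiser import (
    AttentionUNet,
    BankLevel,
    CountLevel,
    DenoiserBank,
    NetConfig,
    TrainConfig,
    build_training_pairs,
    denoise_dynamic,
    denoise_frame,
    gaussian_denoise,
    match_level,
    train_bank,
)
from dynapet.denoiser import autograd as ag
from dynapet.denoiser.bank import _view_windows
from dynapet.frames import ValidationError
from dynapet.phantom import add_poisson_noise, expected_counts


class TestAutogradGradients:
    def test_unet_gradients_match_central_differences(self):
        """Reverse-mode gradients agree with numeric differentiation."""
        ag.set_dtype(np.float64)
        try:
            net = AttentionUNet(NetConfig(depth=1, base_channels=2), seed=0)
            rng = np.random.default_rng(1)
            net.final.w.data = rng.normal(0, 0.1, net.final.w.data.shape)
            x = rng.normal(1, 0.3, (2, 3, 8, 8))
            y = rng.normal(1, 0.3, (2, 1, 8, 8))
            loss = ag.mse(net.forward(x, training=True), y)
            loss.backward()
            check_rng = np.random.default_rng(2)
            for p in net.params():
                flat, gflat = p.data.reshape(-1), p.grad.reshape(-1)
                for idx in check_rng.choice(flat.size, min(3, flat.size), replace=False):
                    eps, old = 1e-6, flat[idx]
                    flat[idx] = old + eps
                    lp = float(ag.mse(net.forward(x, training=True), y).data)
                    flat[idx] = old - eps
                    lm = float(ag.mse(net.forward(x, training=True), y).data)
                    flat[idx] = old
                    num = (lp - lm) / (2 * eps)
                    # absolute floor covers gradients analytically cancelled
                    # by batch normalization (conv biases)
                    assert gflat[idx] == pytest.approx(num, rel=1e-3, abs=1e-9)
        finally:
            ag.set_dtype(np.float32)

    def test_upsample_is_exact_for_constant_and_shape(self):
        x = np.full((1, 2, 4, 4), 3.0)
        out = ag.upsample_bilinear2(ag.Tensor(x))
        assert out.data.shape == (1, 2, 8, 8)
        assert np.allclose(out.data, 3.0)


class TestUnetMechanics:
    def test_parameter_count_near_quarter_million(self):
        net = AttentionUNet(NetConfig(), seed=0)
        assert 1.5e5 < net.n_parameters < 3.5e5

    def test_zeroed_network_is_identity_through_three_views(self):
        """Residual formulation: zero correction branch => exact identity."""
        net = AttentionUNet(NetConfig(), seed=0)  # final conv zero-initialized
        bl = BankLevel(CountLevel(0.1, 1e6), net)
        bank = DenoiserBank([bl])
        rng = np.random.default_rng(0)
        vol = rng.uniform(0.5, 2.0, (16, 16, 16))
        out = denoise_frame(vol, bank, level_override=bl)
        assert np.allclose(out, vol, rtol=1e-5, atol=1e-6)

    def test_zero_frame_passes_through(self):
        net = AttentionUNet(NetConfig(), seed=0)
        bl = BankLevel(CountLevel(0.1, 1e6), net)
        out = denoise_frame(np.zeros((16, 16, 16)), DenoiserBank([bl]),
                            level_override=bl)
        assert np.all(out == 0)

    def test_normalization_round_trip_identity(self):
        """normalize -> un-normalize with no network is the identity."""
        rng = np.random.default_rng(4)
        vol = rng.uniform(0.1, 3.0, (8, 8, 8))
        win, mid_means, (h, w) = _view_windows(vol, 0, mult=8)
        rebuilt = win[:, 1, :h, :w] * np.where(
            vol.mean(axis=(1, 2)) > 0, vol.mean(axis=(1, 2)), 1.0)[:, None, None] \
            / 1.0
        # each channel slice was normalized by its own mean
        restored = win[:, 1] * mid_means[:, None, None]
        assert np.allclose(restored[:, :h, :w], vol)

    def test_state_dict_round_trip(self, tmp_path):
        net = AttentionUNet(NetConfig(), seed=3)
        bl = BankLevel(CountLevel(0.2, 5e5), net, {"n_pairs": 10})
        bank = DenoiserBank([bl])
        bank.save(tmp_path / "bank")
        back = DenoiserBank.load(tmp_path / "bank")
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 1.5, (4, 3, 16, 16))
        assert np.allclose(back.levels[0].net.predict(x), net.predict(x))


class TestTrainingPairs:
    def test_bookkeeping_and_normalization_contract(self, static_frame):
        noisy = add_poisson_noise(static_frame, seed=5)
        factors = [1 / 2, 1 / 5, 1 / 10, 1 / 20, 1 / 60, 1 / 120, 1 / 300]
        pairs = build_training_pairs(noisy, factors, seed=6)
        assert len(pairs) == 7
        for p in pairs:
            n, c, h, w = p.x.shape
            assert c == 3
            # 3 orientations x nonzero slices per orientation
            assert n <= 3 * 32 and n > 0
            # per-slice mean of each normalized nonzero input slice is 1
            means = p.x.mean(axis=(2, 3))
            assert np.allclose(means[means > 1e-9], 1.0, rtol=1e-5)
        # reference counts scale with the factor
        refs = [p.ref_total_counts for p in pairs]
        assert all(a > b for a, b in zip(refs, refs[1:]))

    def test_empty_factor_list_rejected(self, static_frame):
        noisy = add_poisson_noise(static_frame, seed=5)
        with pytest.raises(ValidationError):
            build_training_pairs(noisy, [], seed=0)

    def test_identity_pairs_training_converges(self, static_frame):
        """Degenerate task (input == target) drives the loss toward zero."""
        noisy = add_poisson_noise(static_frame, seed=5)
        pairs = build_training_pairs(noisy, [0.5], seed=1)
        p = pairs[0]
        p.x = p.x[:, :, :, :]
        p.y = p.x[:, 1:2].copy()  # target equals the input middle slice
        cfg = TrainConfig(learning_rate=2e-3, batch_size=16, epochs=4,
                          seed=0, patience=10)
        bank = train_bank([p], NetConfig(), cfg)
        hist = bank.levels[0].meta["loss_history"]
        # the residual net starts at identity, so the initial loss is already
        # tiny; training must still push it further toward zero
        assert hist[-1] < 0.1 * hist[0]
        assert hist[-1] < 2e-6

    def test_training_determinism(self, static_frame):
        noisy = add_poisson_noise(static_frame, seed=5)
        pairs = build_training_pairs(noisy, [0.5], seed=1)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=2, seed=9)
        h1 = train_bank(pairs, NetConfig(), cfg).levels[0].meta["loss_history"]
        pairs2 = build_training_pairs(noisy, [0.5], seed=1)
        h2 = train_bank(pairs2, NetConfig(), cfg).levels[0].meta["loss_history"]
        assert h1 == h2


class TestMatchLevel:
    def _bank(self):
        net = AttentionUNet(NetConfig(depth=1, base_channels=2), seed=0)
        levels = [BankLevel(CountLevel(f, r), net)
                  for f, r in [(0.5, 1e6), (0.1, 2e5), (0.02, 4e4)]]
        return DenoiserBank(levels)

    def test_exact_match(self):
        bank = self._bank()
        assert match_level(2e5, bank).level.factor == 0.1

    def test_clamping_above_and_below(self):
        bank = self._bank()
        assert match_level(1e9, bank).level.factor == 0.5
        assert match_level(1.0, bank).level.factor == 0.02

    def test_geometric_midpoint_ties_to_lower_count_level(self):
        bank = self._bank()
        midpoint = np.sqrt(1e6 * 2e5)
        assert match_level(midpoint, bank).level.factor == 0.1

    def test_zero_counts_warns_and_routes_lowest(self):
        bank = self._bank()
        with pytest.warns(UserWarning):
            assert match_level(0.0, bank).level.factor == 0.02

    def test_scale_consistency_moves_one_level(self):
        """Multiplying a frame's counts by a level ratio shifts the match
        by exactly one level on the ladder."""
        bank = self._bank()
        assert match_level(4e4, bank).level.factor == 0.02
        assert match_level(4e4 * (2e5 / 4e4), bank).level.factor == 0.1


class TestDenoiseDynamic:
    def test_frame_count_and_level_routing(self, static_frame):
        # two-frame image with very different durations/counts
        from dynapet.frames import DynamicImage, FrameSchedule

        vol = np.repeat(static_frame.voxels, 2, axis=3)
        sched = FrameSchedule(((0.0, 5.0), (5.0, 605.0)))
        img = DynamicImage(vol, static_frame.voxel_size_mm, sched,
                           static_frame.calibration)
        net = AttentionUNet(NetConfig(), seed=0)  # zero-init: identity
        counts = expected_counts(img)
        levels = [BankLevel(CountLevel(0.5, counts[..., 1].sum()), net),
                  BankLevel(CountLevel(0.01, counts[..., 0].sum()), net)]
        bank = DenoiserBank(levels)
        out, chosen = denoise_dynamic(img, bank)
        assert out.voxels.shape == img.voxels.shape
        assert out.schedule == img.schedule
        # the short frame routes to the low-count level
        assert chosen == [0.01, 0.5]
        forced, chosen2 = denoise_dynamic(img, bank, level_override=levels[0])
        assert chosen2 == [0.5, 0.5]


class TestGaussianComparator:
    def test_fwhm_zero_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(size=(8, 8, 8))
        assert np.array_equal(gaussian_denoise(vol, 0.0), vol)

    def test_mass_conserved_for_interior_structure(self):
        vol = np.zeros((24, 24, 24))
        vol[10:14, 10:14, 10:14] = 5.0
        out = gaussian_denoise(vol, 6.0)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-3)

    def test_noise_variance_decreases_with_fwhm(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(0, 1, (24, 24, 24))
        variances = [gaussian_denoise(vol, f).var() for f in (0.0, 4.0, 8.0, 12.0)]
        assert all(b < a for a, b in zip(variances, variances[1:]))
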