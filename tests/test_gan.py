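"""Generator/discriminator contracts, SSIM closed forms, and loss arithmetic."""

import numpy as np
import pytest

from cyclect import gan

TINY = gan.GeneratorSpec.tiny()
TINY_D = gan.DiscriminatorSpec.tiny()


@pytest.fixture(scope="module")
def tiny_generator():
    return gan.build_generator(TINY, np.random.default_rng(0))


@pytest.fixture(scope="module")
def tiny_discriminator():
    return gan.build_discriminator(TINY_D, np.random.default_rng(0))


class TestGenerator:
    def test_shape_preserved_and_range_open(self, tiny_generator, rng):
        x = rng.uniform(-1, 1, (16, 16, 16)).astype(np.float32)
        y = tiny_generator(x)
        assert y.shape == x.shape
        assert np.all(y > -1.0) and np.all(y < 1.0)

    def test_rejects_side_not_divisible_by_four(self, tiny_generator):
        with pytest.raises(ValueError):
            tiny_generator(np.zeros((10, 12, 12), dtype=np.float32))

    def test_parameter_count_matches_closed_form(self, tiny_generator):
        """Hand-enumerated layer dimensions for the tiny preset."""
        f, n_res, k = TINY.base_filters, TINY.n_residual, 27  # 3^3 kernels
        expected = (
            (1 * f * k + f)  # encode
            + (f * 2 * f * k + 2 * f)  # down 1
            + (2 * f * 4 * f * k + 4 * f)  # down 2
            + n_res * 2 * (4 * f * 4 * f * k + 4 * f)  # residual conv pairs
            + (4 * f * 2 * f * k + 2 * f)  # up 1
            + (2 * f * f * k + f)  # up 2
            + (f * 1 * k + 1)  # final
        )
        assert tiny_generator.n_parameters() == expected

    def test_deterministic_for_fixed_init(self):
        g1 = gan.build_generator(TINY, np.random.default_rng(3))
        g2 = gan.build_generator(TINY, np.random.default_rng(3))
        x = np.random.default_rng(0).uniform(-1, 1, (8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(g1(x), g2(x))


class TestDiscriminator:
    def test_score_grid_shape_three_halvings(self, tiny_discriminator):
        y = tiny_discriminator(np.zeros((64, 64, 64), dtype=np.float32))
        assert y.shape == (8, 8, 8)  # 64 / 2^3 per axis

    def test_scores_in_unit_interval(self, tiny_discriminator, rng):
        y = tiny_discriminator(rng.uniform(-1, 1, (16, 16, 16)).astype(np.float32))
        assert np.all(y > 0) and np.all(y < 1)

    def test_deterministic_forward(self, tiny_discriminator, rng):
        x = rng.uniform(-1, 1, (16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(tiny_discriminator(x), tiny_discriminator(x))

    def test_rejects_too_small_input(self, tiny_discriminator):
        with pytest.raises(ValueError):
            tiny_discriminator(np.zeros((4, 4, 4), dtype=np.float32))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.uniform(-1, 1, (10, 10, 10))
        assert gan.ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.uniform(-1, 1, (9, 9, 9))
        b = rng.uniform(-1, 1, (9, 9, 9))
        assert gan.ssim(a, b) == pytest.approx(gan.ssim(b, a), abs=1e-12)

    def test_constant_patches_match_zero_variance_closed_form(self):
        c1 = (0.01 * 2.0) ** 2
        a = np.zeros((12, 12, 12))
        b = np.full((12, 12, 12), 0.5)
        assert gan.ssim(a, b) == pytest.approx(c1 / (0.25 + c1), abs=1e-6)

    def test_identical_only_at_one(self, rng):
        a = rng.uniform(-1, 1, (9, 9, 9))
        b = a + 0.05 * rng.standard_normal((9, 9, 9))
        assert gan.ssim(a, b) < 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            gan.ssim(np.zeros((8, 8, 8)), np.zeros((9, 9, 9)))


class TestLosses:
    def test_cycle_loss_zero_on_identical(self, rng):
        a = rng.uniform(-1, 1, (8, 8, 8))
        assert gan.cycle_consistency_loss(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_cycle_loss_constant_patch_closed_form(self):
        x = np.zeros((12, 12, 12))
        xr = np.full((12, 12, 12), 0.5)
        c1 = (0.01 * 2.0) ** 2
        expected = (0.5 + (1.0 - c1 / (0.25 + c1))) / 2.0
        assert gan.cycle_consistency_loss(x, xr) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.7492, abs=5e-4)

    def test_cycle_loss_negation_invariant(self, rng):
        x = rng.uniform(-0.9, 0.9, (9, 9, 9))
        xr = rng.uniform(-0.9, 0.9, (9, 9, 9))
        assert gan.cycle_consistency_loss(x, xr) == pytest.approx(
            gan.cycle_consistency_loss(-x, -xr), abs=1e-10
        )

    def test_identity_loss_cases(self, rng):
        x = np.full((8, 8, 8), 0.2, dtype=np.float32)
        assert gan.identity_loss(lambda p: p, x) == 0.0
        assert gan.identity_loss(lambda p: np.zeros_like(p), x) == pytest.approx(0.2)
        # voxelwise mean is invariant to a joint spatial permutation
        y = rng.uniform(-1, 1, (8, 8, 8))
        perm = lambda a: a.transpose(2, 0, 1)[::-1]
        assert gan.identity_loss(lambda p: np.tanh(p), y) == pytest.approx(
            gan.identity_loss(lambda p: np.tanh(p), perm(y)), abs=1e-7
        )

    def test_adversarial_losses_closed_values(self):
        ones = np.ones((2, 2, 2))
        zeros = np.zeros((2, 2, 2))
        half = np.full((2, 2, 2), 0.5)
        assert gan.adversarial_generator_loss(ones) == 0.0
        assert gan.adversarial_discriminator_loss(ones, zeros) == 0.0
        assert gan.adversarial_discriminator_loss(half, half) == pytest.approx(0.25)

    def test_total_generator_loss_arithmetic(self):
        w = gan.LossWeights(lambda_identity=10.0)
        assert gan.total_generator_loss(1.0, 0.2, 0.05, w) == pytest.approx(1.7)
        assert gan.total_generator_loss(0.0, 0.0, 0.0, w) == 0.0
        w0 = gan.LossWeights(lambda_identity=0.0)
        assert gan.total_generator_loss(0.3, 0.4, 99.0, w0) == pytest.approx(0.7)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        g = gan.build_generator(TINY, np.random.default_rng(5))
        d = gan.build_discriminator(TINY_D, np.random.default_rng(6))
        path = tmp_path / "ckpt.npz"
        gan.save_checkpoint(path, {"g_ab": g, "d_a": d}, meta={"seed": 5})
        models, meta = gan.load_checkpoint(path)
        assert meta == {"seed": 5}
        x = rng.uniform(-1, 1, (8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(models["g_ab"](x), g(x))
        np.testing.assert_array_equal(models["d_a"](x), d(x))
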