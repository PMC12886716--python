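"""Training-objective oracles: closed forms and brute-force references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtmihc.autodiff import Tensor
from virtmihc.losses import LossCoefficients, bce, discriminator_loss, \
    generator_loss, huber, mse, psnr, registration_loss, smth, tv

from oracles import bce_oracle, huber_oracle, mse_oracle, numerical_gradient, \
    psnr_oracle, smth_oracle, tv_oracle

RNG = np.random.default_rng(7)


class TestHuber:
    def test_zero_for_equal_images(self):
        a = RNG.random((3, 8, 8))
        assert huber(a, a) == 0.0

    @pytest.mark.parametrize("diff,expected", [(0.5, 0.125), (2.0, 1.5)])
    def test_single_pixel_closed_form(self, diff, expected):
        assert huber(np.array([[diff]]), np.array([[0.0]]), phi=1.0) \
            == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_images(self):
        a, b = RNG.random((2, 16, 16)), 3 * RNG.random((2, 16, 16))
        assert huber(a, b) == pytest.approx(huber_oracle(a, b), abs=1e-9)

    def test_symmetric(self):
        a, b = RNG.random((4, 4)), RNG.random((4, 4))
        assert huber(a, b) == pytest.approx(huber(b, a), abs=1e-12)

    def test_continuous_and_differentiable_at_threshold(self):
        # both branches meet at value phi/2; slopes approach 1 from each side
        phi = 1.0
        eps = 1e-7
        below = huber(np.array([[phi - eps]]), np.array([[0.0]]), phi)
        above = huber(np.array([[phi + eps]]), np.array([[0.0]]), phi)
        assert below == pytest.approx(phi / 2, abs=1e-6)
        assert above == pytest.approx(phi / 2, abs=1e-6)
        slope_below = (huber(np.array([[phi - eps]]), np.array([[0.0]]), phi)
                       - huber(np.array([[phi - 3 * eps]]),
                               np.array([[0.0]]), phi)) / (2 * eps)
        slope_above = (huber(np.array([[phi + 3 * eps]]),
                             np.array([[0.0]]), phi)
                       - huber(np.array([[phi + eps]]),
                               np.array([[0.0]]), phi)) / (2 * eps)
        assert slope_below == pytest.approx(slope_above, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            huber(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBCE:
    def test_half_probability_gives_ln2_for_both_labels(self):
        assert bce(0.5, 1) == pytest.approx(np.log(2), abs=1e-12)
        assert bce(0.5, 0) == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_correct_score_approaches_zero(self):
        assert bce(1 - 1e-9, 1) < 1e-8

    def test_matches_closed_form(self):
        for p in (0.1, 0.37, 0.9):
            for label in (0, 1):
                assert bce(p, label) == pytest.approx(
                    bce_oracle(p, label), abs=1e-9)

    def test_logits_form_is_stable_and_consistent(self):
        for z in (-3.0, 0.0, 2.5):
            p = 1 / (1 + np.exp(-z))
            assert bce(z, 1, from_logits=True) == pytest.approx(
                bce(p, 1), abs=1e-9)
        assert np.isfinite(bce(500.0, 0, from_logits=True))
        assert np.isfinite(bce(-500.0, 1, from_logits=True))


class TestTV:
    def test_constant_image_is_zero(self):
        assert tv(np.full((5, 5), 3.3)) == 0.0

    def test_two_by_two_example(self):
        assert tv(np.array([[0.0, 1.0], [0.0, 1.0]])) == pytest.approx(2.0)

    def test_checkerboard_closed_form(self):
        k = 6
        board = np.indices((k, k)).sum(axis=0) % 2
        # every adjacent pair differs by 1: k*(k-1) vertical + horizontal
        assert tv(board.astype(float)) == pytest.approx(2 * k * (k - 1))

    def test_matches_bruteforce_multichannel(self):
        img = RNG.random((3, 9, 7))
        assert tv(img) == pytest.approx(tv_oracle(img), abs=1e-9)


class TestSMTH:
    def test_constant_field_is_zero(self):
        assert smth(np.full((2, 6, 6), 2.5)) == 0.0

    def test_linear_ramp_normalization(self):
        h = w = 5
        field = np.zeros((2, h, w))
        field[0] = np.arange(h)[:, None]      # unit forward differences
        # (h-1)*w unit differences in one direction, one component
        assert smth(field) == pytest.approx((h - 1) * w / (h * w), abs=1e-12)

    def test_quadratic_homogeneity(self):
        f = RNG.random((2, 8, 8))
        assert smth(2 * f) == pytest.approx(4 * smth(f), rel=1e-12)

    def test_matches_bruteforce(self):
        f = RNG.standard_normal((2, 7, 6))
        assert smth(f) == pytest.approx(smth_oracle(f), abs=1e-9)


class TestComposites:
    def test_generator_loss_composes_its_three_oracles(self):
        target = RNG.random((1, 3, 8, 8)).astype(np.float64)
        field = np.zeros((1, 2, 8, 8))
        coeffs = LossCoefficients()
        total, comp = generator_loss(target, target, 0.0, field,
                                     coeffs=coeffs)   # logit 0 -> p=0.5
        assert comp["l_huber"] == 0.0
        assert comp["l_adv"] == pytest.approx(np.log(2), abs=1e-9)
        assert comp["l_tv"] == pytest.approx(tv_oracle(target), abs=1e-9)
        assert total == pytest.approx(10 * np.log(2)
                                      + 1e-4 * tv_oracle(target), abs=1e-7)

    def test_generator_loss_components_sum_to_total(self):
        g = RNG.random((1, 3, 8, 8))
        t = RNG.random((1, 3, 8, 8))
        field = RNG.uniform(-1, 1, (1, 2, 8, 8))
        coeffs = LossCoefficients()
        total, comp = generator_loss(g, t, 0.3, field, coeffs=coeffs)
        recomposed = (coeffs.alpha * comp["l_huber"]
                      + coeffs.beta * comp["l_adv"]
                      + coeffs.gamma * comp["l_tv"])
        assert total == pytest.approx(recomposed, abs=1e-9)

    def test_generator_loss_requires_field(self):
        a = np.zeros((1, 3, 8, 8))
        with pytest.raises(ValueError):
            generator_loss(a, a, 0.0, None)

    def test_discriminator_loss_closed_form_and_limits(self):
        assert discriminator_loss(0.0, 0.0) == pytest.approx(2 * np.log(2))
        assert discriminator_loss(-30.0, 30.0) < 1e-8

    def test_registration_loss_zero_when_aligned(self):
        t = RNG.random((1, 3, 8, 8))
        total, _ = registration_loss(t, t, np.zeros((1, 2, 8, 8)))
        assert total == 0.0

    def test_registration_loss_constant_field_pays_no_smoothness(self):
        t = RNG.random((1, 3, 32, 32))
        field = np.zeros((1, 2, 32, 32))
        field[:, 1] = 3.0
        from oracles import shift_oracle
        shifted = shift_oracle(t[0], 0, -3)[None]   # inverse of gather +3
        total, comp = registration_loss(shifted, t, field)
        assert comp["l_smth"] == 0.0                # constant field is free
        # interior re-aligns exactly; only the 3-column clamped border pays
        warped = np.asarray(
            __import__("virtmihc.model", fromlist=["warp"]).warp(
                shifted, field[0]))
        assert np.allclose(warped[..., :, :-3], t[..., :, :-3], atol=1e-12)
        assert comp["l_reg"] < (3 / 32) * huber(shifted, t) * 2


class TestFidelityMetrics:
    def test_known_offset_gives_psnr_twenty(self):
        b = RNG.random((8, 8)) * 0.9
        b.flat[0] = 1.0                     # max(b) = 1
        a = b - 0.1
        assert mse(a, b) == pytest.approx(0.01, abs=1e-12)
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-9)

    def test_identical_images_hit_sentinel(self):
        a = RNG.random((4, 4))
        assert psnr(a, a) == float("inf")

    def test_joint_scaling_shifts_psnr_consistently(self):
        b = RNG.random((8, 8)) + 0.5
        a = b + RNG.normal(0, 0.05, b.shape)
        # scaling both halves peak and halves RMSE: ratio unchanged
        assert psnr(0.5 * a, 0.5 * b) == pytest.approx(psnr(a, b), rel=1e-9)

    def test_matches_bruteforce(self):
        a, b = RNG.random((5, 5)), RNG.random((5, 5))
        assert mse(a, b) == pytest.approx(mse_oracle(a, b), abs=1e-12)
        assert psnr(a, b) == pytest.approx(psnr_oracle(a, b), abs=1e-9)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_losses_are_nonnegative_and_zero_conditions(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.random((2, 6, 6)), rng.random((2, 6, 6))
    f = rng.standard_normal((2, 6, 6))
    assert huber(a, b) >= 0
    assert tv(a) >= 0
    assert smth(f) >= 0
    assert (huber(a, b) == 0) == np.array_equal(a, b)
    assert (smth(f) == 0) == (np.ptp(f[0]) == 0 and np.ptp(f[1]) == 0)


@pytest.mark.parametrize("name,loss_fn", [
    ("huber", lambda t, other: huber(t, other)),
    ("tv", lambda t, other: tv(t)),
    ("smth", lambda t, other: smth(t)),
    ("bce_logits", lambda t, other: bce(t, 1, from_logits=True)),
])
def test_loss_gradients_match_finite_differences(name, loss_fn):
    # inputs keep |a-b| below phi so the Huber check avoids the kink
    x = RNG.random((2, 8, 8)) * 0.4
    other = RNG.random((2, 8, 8)) * 0.4

    def value(v):
        out = loss_fn(Tensor(v), other)
        return float(out.data) if hasattr(out, "data") else float(out)

    t = Tensor(x, requires_grad=True)
    loss_fn(t, other).backward()
    num = numerical_gradient(value, x.copy())
    assert np.allclose(t.grad, num, rtol=1e-4, atol=1e-7), name
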