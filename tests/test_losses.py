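"""Every objective against independent scalar-loop oracles and closed forms."""

import numpy as np
import pytest

from virtstain import losses as L
from virtstain.nn import Tensor, as_tensor

RNG = np.random.default_rng(42)


def loop_mean_abs(a, b):
    total, n = 0.0, 0
    for x, y in zip(a.ravel(), b.ravel()):
        total += abs(x - y)
        n += 1
    return total / n


class TestPixelL1:
    def test_zero_on_identical(self):
        x = RNG.normal(size=(2, 3, 4, 4))
        assert L.pixel_l1(x, x).item() == 0.0

    def test_known_magnitudes(self):
        y_hat = np.array([1.0, -1.0, 0.5, 0.0])
        y = np.zeros(4)
        assert L.pixel_l1(y_hat, y).item() == pytest.approx(0.625)

    def test_matches_loop_oracle(self):
        a, b = RNG.normal(size=(2, 3, 4, 4)), RNG.normal(size=(2, 3, 4, 4))
        assert L.pixel_l1(a, b).item() == pytest.approx(loop_mean_abs(a, b), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            L.pixel_l1(np.zeros((2, 2)), np.zeros((3, 2)))


class TestCycle:
    def test_identity_maps_give_zero(self):
        ident = lambda t: t
        x, y = Tensor(RNG.normal(size=(1, 3, 4, 4))), Tensor(RNG.normal(size=(1, 3, 4, 4)))
        assert L.cycle_loss(ident, ident, x, y).item() == 0.0

    def test_negation_is_an_involution(self):
        neg = lambda t: -as_tensor(t)
        x, y = Tensor(RNG.normal(size=(1, 3, 4, 4))), Tensor(RNG.normal(size=(1, 3, 4, 4)))
        assert L.cycle_loss(neg, neg, x, y).item() == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self):
        a = RNG.normal(size=(1, 3, 4, 4))
        b = RNG.normal(size=(1, 3, 4, 4))
        F = lambda t: as_tensor(t) * 0.5
        G = lambda t: as_tensor(t) + 1.0
        got = L.cycle_loss(F, G, Tensor(a), Tensor(b)).item()
        expected = loop_mean_abs(0.5 * (a + 1.0), a) + loop_mean_abs(0.5 * b + 1.0, b)
        assert got == pytest.approx(expected, abs=1e-6)


class TestDomainConsistency:
    def test_constant_judge_at_same_target(self):
        C = lambda a, b: as_tensor(np.ones((2, 1)))
        y1 = y2 = np.zeros((2, 3))
        loss_c, _ = L.domain_consistency_loss(C, np.zeros((2, 3)), y1, y2, None)
        # same-domain term (C - 1)^2 vanishes; mixed term is (1 - 0)^2 = 1
        assert loss_c.item() == pytest.approx(1.0)

    def test_constant_half_judge_with_swapped_targets(self):
        C = lambda a, b: as_tensor(np.full((2, 1), 0.5))
        y = np.zeros((2, 3))
        loss_c, loss_g = L.domain_consistency_loss(C, y, y, y, None, targets=(0.0, 1.0))
        assert loss_c.item() == pytest.approx(0.5)  # 0.25 + 0.25
        assert loss_g.item() == pytest.approx(0.25)

    def test_matches_printed_formula_oracle(self):
        w = RNG.normal(size=(3, 1))

        def C(a, b):
            return (as_tensor(a) + 2.0 * as_tensor(b)) @ Tensor(w)

        y1 = RNG.normal(size=(2, 3))
        y2 = RNG.normal(size=(2, 3))
        fake = RNG.normal(size=(2, 3))
        printed = L.domain_consistency_loss(C, fake, y1, y2, None, as_printed=True)
        same = (y1 + 2 * y2) @ w
        mixed = (y1 + 2 * fake) @ w
        expected = np.mean(same ** 2) + np.mean((1 - mixed) ** 2)
        assert printed.item() == pytest.approx(expected, abs=1e-6)

        loss_c, loss_g = L.domain_consistency_loss(C, fake, y1, y2, None)
        assert loss_c.item() == pytest.approx(
            np.mean((same - 1) ** 2) + np.mean(mixed ** 2), abs=1e-6)
        assert loss_g.item() == pytest.approx(np.mean((mixed - 1) ** 2), abs=1e-6)


def linear_sum_critic(x, y):
    return as_tensor(y).sum(axis=tuple(range(1, as_tensor(y).ndim)))


class TestWganGp:
    def test_linear_critic_penalty_closed_form(self):
        # D = sum over the M=4 target elements -> grad all-ones, |grad| = 2
        y_real = RNG.normal(size=(3, 4))
        y_fake = RNG.normal(size=(3, 4))
        pen = L.gradient_penalty(linear_sum_critic, 0, y_real, y_fake,
                                 np.random.default_rng(0))
        assert pen.item() == pytest.approx((2.0 - 1.0) ** 2, abs=1e-9)

    def test_scaled_critic_zero_penalty(self):
        scaled = lambda x, y: linear_sum_critic(x, y) * 0.5  # 1/sqrt(4)
        pen = L.gradient_penalty(scaled, 0, RNG.normal(size=(3, 4)),
                                 RNG.normal(size=(3, 4)), np.random.default_rng(0))
        assert pen.item() == pytest.approx(0.0, abs=1e-9)

    def test_penalty_matches_finite_difference_norm(self):
        w = RNG.normal(size=(4, 2))

        def D(x, y):
            return (as_tensor(y) @ Tensor(w)).tanh().sum(axis=1)

        y_real = RNG.normal(size=(2, 4))
        y_fake = RNG.normal(size=(2, 4))
        pen = L.gradient_penalty(D, 0, y_real, y_fake, np.random.default_rng(5))

        eps = np.random.default_rng(5).uniform(size=(2, 1))
        interp = eps * y_real + (1 - eps) * y_fake

        def scalar_d(v):
            return np.sum(np.tanh(v @ w))

        norms = []
        for row in interp:
            g = np.zeros(4)
            for j in range(4):
                rp, rm = row.copy(), row.copy()
                rp[j] += 1e-5
                rm[j] -= 1e-5
                g[j] = (scalar_d(rp[None]) - scalar_d(rm[None])) / 2e-5
            norms.append(np.linalg.norm(g))
        expected = np.mean([(n - 1.0) ** 2 for n in norms])
        assert pen.item() == pytest.approx(expected, abs=1e-3)

    def test_critic_loss_translation_invariant(self):
        y_real, y_fake = RNG.normal(size=(2, 4)), RNG.normal(size=(2, 4))
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        base, _ = L.adv_wgan_gp(linear_sum_critic, 0, y_real, y_fake, 10.0, rng_a)
        shifted_critic = lambda x, y: linear_sum_critic(x, y) + 123.0
        shifted, _ = L.adv_wgan_gp(shifted_critic, 0, y_real, y_fake, 10.0, rng_b)
        assert base.item() == pytest.approx(shifted.item(), abs=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            L.adv_wgan_gp(linear_sum_critic, 0, np.zeros((1, 4)),
                          np.zeros((1, 4)), lambda_gp=-1.0)


class TestLogisticR1:
    def test_zero_logits_give_two_log_two(self):
        D = lambda x, y: as_tensor(np.zeros((3, 1)))
        ld, lg = L.adv_logistic_r1(D, 0, np.zeros((3, 2)), np.zeros((3, 2)),
                                   gamma_r1=0.0)
        assert ld.item() == pytest.approx(2 * np.log(2))
        assert lg.item() == pytest.approx(np.log(2))

    def test_linear_critic_r1_closed_form(self):
        gamma, M = 6.0, 4
        y = RNG.normal(size=(2, M))
        r1 = L.r1_penalty(linear_sum_critic, 0, y)
        assert r1.item() == pytest.approx(M)
        ld, _ = L.adv_logistic_r1(linear_sum_critic, 0, y, y, gamma_r1=gamma)
        base, _ = L.adv_logistic_r1(linear_sum_critic, 0, y, y, gamma_r1=0.0)
        assert ld.item() - base.item() == pytest.approx(gamma / 2 * M, abs=1e-9)

    def test_matches_softplus_oracle(self):
        w = RNG.normal(size=(4, 1))
        D = lambda x, y: as_tensor(y) @ Tensor(w)
        y_real, y_fake = RNG.normal(size=(3, 4)), RNG.normal(size=(3, 4))
        ld, lg = L.adv_logistic_r1(D, 0, y_real, y_fake, gamma_r1=0.0)
        sp = lambda z: np.logaddexp(0.0, z)
        expected_d = sp(-(y_real @ w)).mean() + sp(y_fake @ w).mean()
        expected_g = sp(-(y_fake @ w)).mean()
        assert ld.item() == pytest.approx(expected_d, abs=1e-6)
        assert lg.item() == pytest.approx(expected_g, abs=1e-6)


class TestL2Adversarial:
    def test_perfect_critic_zero_loss(self):
        D = lambda x, y: as_tensor(np.ones((2, 1)) if y.data.sum() > 0 else np.zeros((2, 1)))
        real = np.ones((2, 3))
        fake = -np.ones((2, 3))
        ld, _ = L.adv_l2(D, 0, real, fake)
        assert ld.item() == pytest.approx(0.0)

    def test_half_critic_quarter_terms(self):
        D = lambda x, y: as_tensor(np.full((2, 1), 0.5))
        ld, lg = L.adv_l2(D, 0, np.zeros((2, 3)), np.zeros((2, 3)))
        assert ld.item() == pytest.approx(0.5)
        assert lg.item() == pytest.approx(0.25)

    def test_matches_formula_oracle(self):
        w = RNG.normal(size=(3, 1))
        D = lambda x, y: as_tensor(y) @ Tensor(w)
        real, fake = RNG.normal(size=(2, 3)), RNG.normal(size=(2, 3))
        ld, lg = L.adv_l2(D, 0, real, fake)
        assert ld.item() == pytest.approx(
            np.mean((real @ w - 1) ** 2) + np.mean((fake @ w) ** 2), abs=1e-6)
        assert lg.item() == pytest.approx(np.mean((fake @ w - 1) ** 2), abs=1e-6)


class TestFeatureMatching:
    def test_zero_on_identical(self):
        feats = [RNG.normal(size=(2, 3, 2, 2)) for _ in range(3)]
        assert L.feature_matching(feats, [f.copy() for f in feats]).item() == 0.0

    def test_layer_average(self):
        fr = [np.zeros((1, 1)), np.zeros((1, 1))]
        ff = [np.full((1, 1), 0.2), np.full((1, 1), 0.4)]
        assert L.feature_matching(fr, ff).item() == pytest.approx(0.3)

    def test_matches_loop_oracle(self):
        fr = [RNG.normal(size=(2, 3, 2, 2)) for _ in range(3)]
        ff = [RNG.normal(size=(2, 3, 2, 2)) for _ in range(3)]
        expected = np.mean([loop_mean_abs(a, b) for a, b in zip(fr, ff)])
        assert L.feature_matching(fr, ff).item() == pytest.approx(expected, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            L.feature_matching([np.zeros(2)], [])


class TestTotal:
    def test_weighted_sums(self):
        w0 = L.LossWeights(lambda_pix=0.0, lambda_fm=0.0)
        assert L.total_loss(1.0, 2.0, 3.0, w0).item() == pytest.approx(1.0)
        w = L.LossWeights(lambda_pix=10.0, lambda_fm=10.0)
        assert L.total_loss(1.0, 2.0, 3.0, w).item() == pytest.approx(51.0)

    def test_random_linearity(self):
        a, p, f = RNG.normal(size=3)
        w = L.LossWeights(lambda_pix=float(RNG.uniform(0, 5)),
                          lambda_fm=float(RNG.uniform(0, 5)))
        got = L.total_loss(a, p, f, w).item()
        assert got == pytest.approx(a + w.lambda_pix * p + w.lambda_fm * f)

    def test_nonfinite_component_rejected(self):
        with pytest.raises(FloatingPointError):
            L.total_loss(np.nan, 0.0, 0.0, L.LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda_pix=-1.0)
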