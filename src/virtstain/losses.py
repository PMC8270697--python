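"""Training objectives for both stages.

Stage 1 (unpaired translation): cycle consistency plus the domain-consistency
game, in which an auxiliary two-input discriminator judges whether two images
come from the same domain; buffered augmented reals form the "same" pairs and
a generated image paired with a buffered real forms the "mixed" pair.

Stage 2 (paired stain transfer): an adversarial term (WGAN with gradient
penalty by default, with least-squares and non-saturating-logistic + R1
alternatives for ablation), a pixel-wise L1 term, and a feature-matching
term over the critic's per-layer activations. The total objective is

    L = L_adv + lambda_pix * L_pix + lambda_fm * L_fm

As printed, the domain-consistency objective gives its maximizing player an
unbounded payoff, so the trainable form here is the least-squares convention
(same-domain target 1, mixed target 0, both players minimize); the printed
form remains available via ``as_printed=True`` for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, grad

__all__ = [
    "LossWeights",
    "cycle_loss",
    "domain_consistency_loss",
    "adv_wgan_gp",
    "adv_logistic_r1",
    "adv_l2",
    "pixel_l1",
    "feature_matching",
    "total_loss",
]

ADV_VARIANTS = ("l2", "wgan_gp", "logistic_r1")


@dataclass
class LossWeights:
    lambda_gp: float = 10.0
    lambda_pix: float = 100.0
    lambda_fm: float = 10.0
    lambda_cyc: float = 10.0
    lambda_dc: float = 1.0
    gamma_r1: float = 10.0
    adv_variant: str = "wgan_gp"

    def __post_init__(self):
        for name in ("lambda_gp", "lambda_pix", "lambda_fm", "lambda_cyc",
                     "lambda_dc", "gamma_r1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.adv_variant not in ADV_VARIANTS:
            raise ValueError(f"adv_variant must be one of {ADV_VARIANTS}")


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def pixel_l1(y_hat, y) -> Tensor:
    """Mean absolute difference over all elements."""
    y_hat, y = as_tensor(y_hat), as_tensor(y)
    _check_same_shape(y_hat, y)
    return (y_hat - y).abs().mean()


def cycle_loss(F, G, x, y) -> Tensor:
    """Two-sided cycle reconstruction: |F(G(x)) - x| + |G(F(y)) - y|."""
    x, y = as_tensor(x), as_tensor(y)
    fx = F(G(x))
    gy = G(F(y))
    _check_same_shape(fx, x)
    _check_same_shape(gy, y)
    return (fx - x).abs().mean() + (gy - y).abs().mean()


def domain_consistency_loss(C, G, aug_y1, aug_y2, x, targets=(1.0, 0.0),
                            as_printed: bool = False):
    """Domain-consistency objectives.

    ``aug_y1``/``aug_y2`` are two augmented same-domain batches drawn from
    the input buffer; ``G(x)`` is the opposing generator's output. With the
    least-squares convention and targets ``(a, b)``:

        loss_C = E[(C(y1, y2) - a)^2] + E[(C(y1, G(x)) - b)^2]
        loss_G = E[(C(y1, G(x)) - a)^2]

    ``as_printed=True`` instead evaluates the formula as published,
    E[C(y1, y2)^2] + E[(1 - C(y1, G(x)))^2], and returns that single scalar.
    """
    aug_y1, aug_y2 = as_tensor(aug_y1), as_tensor(aug_y2)
    _check_same_shape(aug_y1, aug_y2)
    fake = G(x) if callable(G) else as_tensor(G)
    same = C(aug_y1, aug_y2)
    mixed = C(aug_y1, fake)
    if as_printed:
        return (same ** 2.0).mean() + ((1.0 - mixed) ** 2.0).mean()
    a, b = targets
    loss_c = ((same - a) ** 2.0).mean() + ((mixed - b) ** 2.0).mean()
    loss_g = ((mixed - a) ** 2.0).mean()
    return loss_c, loss_g


def _critic_score(D, x, y) -> Tensor:
    """Apply a critic that may be conditional (x, y) or unconditional (y)."""
    return D(x, y) if x is not None else D(y)


def gradient_penalty(D, x, y_real, y_fake, rng: np.random.Generator) -> Tensor:
    """E[(||grad_target D(x, interp)||_2 - 1)^2], condition held fixed.

    The interpolate mixes the positive sample and the generated sample with
    a per-sample epsilon ~ U(0, 1); the result is differentiable w.r.t. the
    critic parameters (double backward through the critic).
    """
    y_real, y_fake = as_tensor(y_real), as_tensor(y_fake)
    _check_same_shape(y_real, y_fake)
    n = y_real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=(n,) + (1,) * (y_real.ndim - 1))
    interp = Tensor(eps * y_real.data + (1.0 - eps) * y_fake.data, requires_grad=True)
    score = _critic_score(D, x, interp).sum()
    (g,) = grad(score, [interp], create_graph=True)
    axes = tuple(range(1, y_real.ndim))
    norm = ((g ** 2.0).sum(axis=axes) + 1e-12).sqrt()
    return ((norm - 1.0) ** 2.0).mean()


def adv_wgan_gp(D, x, y_real, y_fake, lambda_gp: float = 10.0,
                rng: np.random.Generator | None = None):
    """Wasserstein critic/generator objectives with gradient penalty.

    Returns ``(loss_D, loss_G)`` where the critic minimizes
    E[D(x, G(x))] - E[D(x, y)] + lambda_gp * GP and the generator minimizes
    -E[D(x, G(x))]. Adding a constant to D leaves loss_D unchanged.
    """
    if lambda_gp < 0:
        raise ValueError("lambda_gp must be >= 0")
    rng = rng or np.random.default_rng()
    y_real, y_fake = as_tensor(y_real), as_tensor(y_fake)
    _check_same_shape(y_real, y_fake)
    fake_score = _critic_score(D, x, y_fake).mean()
    real_score = _critic_score(D, x, y_real).mean()
    loss_d = fake_score - real_score
    if lambda_gp > 0:
        loss_d = loss_d + lambda_gp * gradient_penalty(D, x, y_real, y_fake, rng)
    loss_g = -fake_score
    return loss_d, loss_g


def r1_penalty(D, x, y_real) -> Tensor:
    """E[||grad_y D(x, y)||^2] at real samples (no square root)."""
    y_real = as_tensor(y_real)
    yin = Tensor(y_real.data, requires_grad=True)
    score = _critic_score(D, x, yin).sum()
    (g,) = grad(score, [yin], create_graph=True)
    axes = tuple(range(1, yin.ndim))
    return (g ** 2.0).sum(axis=axes).mean()


def adv_logistic_r1(D, x, y_real, y_fake, gamma_r1: float = 10.0):
    """Non-saturating logistic GAN objectives with R1 regularization.

    loss_D = E[softplus(-D(real))] + E[softplus(D(fake))] + (gamma/2) * R1;
    loss_G = E[softplus(-D(fake))].
    """
    if gamma_r1 < 0:
        raise ValueError("gamma_r1 must be >= 0")
    y_real, y_fake = as_tensor(y_real), as_tensor(y_fake)
    _check_same_shape(y_real, y_fake)
    real_logits = _critic_score(D, x, y_real)
    fake_logits = _critic_score(D, x, y_fake)
    loss_d = (-real_logits).softplus().mean() + fake_logits.softplus().mean()
    if gamma_r1 > 0:
        loss_d = loss_d + (gamma_r1 / 2.0) * r1_penalty(D, x, y_real)
    loss_g = (-fake_logits).softplus().mean()
    return loss_d, loss_g


def adv_l2(D, x, y_real, y_fake):
    """Least-squares GAN objectives with targets 1 (real) / 0 (fake)."""
    y_real, y_fake = as_tensor(y_real), as_tensor(y_fake)
    _check_same_shape(y_real, y_fake)
    real = _critic_score(D, x, y_real)
    fake = _critic_score(D, x, y_fake)
    loss_d = ((real - 1.0) ** 2.0).mean() + (fake ** 2.0).mean()
    loss_g = ((fake - 1.0) ** 2.0).mean()
    return loss_d, loss_g


def feature_matching(feats_real, feats_fake) -> Tensor:
    """Mean over critic layers of the mean absolute feature difference."""
    if len(feats_real) != len(feats_fake):
        raise ValueError("feature lists must have equal length")
    if not feats_real:
        raise ValueError("feature lists must be non-empty")
    total = None
    for fr, ff in zip(feats_real, feats_fake):
        fr, ff = as_tensor(fr), as_tensor(ff)
        _check_same_shape(fr, ff)
        term = (fr - ff).abs().mean()
        total = term if total is None else total + term
    return total * (1.0 / len(feats_real))


def total_loss(adv, pix, fm, w: LossWeights) -> Tensor:
    """Weighted stage-2 objective: adv + lambda_pix * pix + lambda_fm * fm."""
    parts = [as_tensor(adv), as_tensor(pix), as_tensor(fm)]
    for p in parts:
        if not np.all(np.isfinite(p.data)):
            raise FloatingPointError("non-finite loss component")
    return parts[0] + w.lambda_pix * parts[1] + w.lambda_fm * parts[2]
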