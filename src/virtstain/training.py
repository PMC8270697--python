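"""Two-stage training orchestration.

Stage 1 learns, from *unpaired* pools of stained and unstained tiles, a
translator that synthesizes a pseudo-unstained (autofluorescence-like) image
for every stained tile. It is a CycleGAN game extended with per-domain input
buffers of heavily augmented reals and a domain-consistency discriminator
per direction; the generators are separable-convolution networks. Running
the trained forward generator over the stained pool yields an aligned paired
dataset.

Stage 2 trains the virtual-staining generator (PFFN by default) on the
paired set with the weighted objective: adversarial (WGAN-GP default) +
pixel L1 + feature matching over the conditional patch critic's layers.

Both stages are wrapped as sklearn-style estimators (``fit`` /
``transform``, fitted attributes with trailing underscores) with thin
functional wrappers preserved for script use.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import losses as L
from . import networks as net
from .augment import AugmentationPolicy, InputBuffer, augment
from .nn import Adam, Tensor, backward, no_grad
from .types import STAINED, UNSTAINED, ImageTile, PairedSample

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "Stage1Translator",
    "PairedStainer",
    "train_stage1",
    "synthesize_pairs",
    "train_stage2",
    "stain",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Shared training knobs; see the stage estimators for defaults."""

    stage: int = 2
    steps: int = 300
    batch_size: int = 2
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.9)
    critic_steps: int = 1
    seed: int = 0
    buffer_capacity: int = 256
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    network: net.NetworkConfig = field(default_factory=net.NetworkConfig)
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch size must be positive")


@dataclass
class Checkpoint:
    """Serializable model snapshot; ``load(save(c))`` reproduces forwards."""

    kind: str  # "stage1" | "stage2"
    config: dict
    state: dict  # name -> {param: array}
    step: int = 0

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        flat = {}
        for netname, sd in self.state.items():
            for k, v in sd.items():
                flat[f"{netname}::{k}"] = v
        meta = json.dumps({"kind": self.kind, "config": self.config, "step": self.step})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **flat)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state: dict = {}
        for key in z.files:
            if key == "__meta__":
                continue
            netname, pname = key.split("::", 1)
            state.setdefault(netname, {})[pname] = z[key]
    return Checkpoint(meta["kind"], meta["config"], state, meta["step"])


def _to_batch(tiles) -> Tensor:
    """Stack tiles into an (N, 3, H, W) tensor on the [-1, 1] model scale."""
    arr = np.stack([t.to_unit() for t in tiles]).transpose(0, 3, 1, 2)
    return Tensor(arr)


def _from_batch(t: Tensor, domain: str, value_range=(0.0, 1.0)) -> list[ImageTile]:
    arr = t.data.transpose(0, 2, 3, 1)
    return [ImageTile.from_unit(a, domain, value_range) for a in arr]


def _finite_or_raise(entry: dict, step: int) -> None:
    for k, v in entry.items():
        if isinstance(v, float) and not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss {k!r} at step {step}")


class Stage1Translator(BaseEstimator, TransformerMixin):
    """Unpaired stained -> unstained translator (domain-consistency CycleGAN).

    Parameters mirror the training configuration: ``generator`` chooses the
    residual-instance-norm baseline ("resnet") or the separable-convolution
    redesign ("separable", default); ``lambda_dc`` weighs the
    domain-consistency game and ``lambda_cyc`` the cycle reconstruction.
    ``fit(stained_tiles, unstained_tiles)`` trains both directions; the
    fitted ``transform`` maps stained tiles to pseudo-unstained tiles.
    """

    def __init__(self, steps=100, batch_size=2, lr=2e-4, base_width=8,
                 n_res_blocks=3, generator="separable", lambda_cyc=10.0,
                 lambda_dc=1.0, lambda_adv=1.0, buffer_capacity=64,
                 policy=None, seed=0):
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.base_width = base_width
        self.n_res_blocks = n_res_blocks
        self.generator = generator
        self.lambda_cyc = lambda_cyc
        self.lambda_dc = lambda_dc
        self.lambda_adv = lambda_adv
        self.buffer_capacity = buffer_capacity
        self.policy = policy
        self.seed = seed

    # -- construction ---------------------------------------------------
    def _build(self):
        cfg = net.NetworkConfig(base_width=self.base_width,
                                n_res_blocks=self.n_res_blocks,
                                conditional=False, rng_seed=self.seed)
        build = (net.build_sep_generator if self.generator == "separable"
                 else net.build_resnet_generator)
        self.g1_ = build(cfg)   # stained -> unstained
        self.g2_ = build(cfg)   # unstained -> stained
        self.dx_ = net.build_patch_critic(cfg)   # judges stained domain
        self.dy_ = net.build_patch_critic(cfg)   # judges unstained domain
        self.c1_ = net.build_domain_consistency_net(cfg)  # unstained pairs
        self.c2_ = net.build_domain_consistency_net(cfg)  # stained pairs

    def fit(self, X, y=None):
        """Train on unpaired pools: X = stained tiles, y = unstained tiles."""
        stained, unstained = list(X), list(y or [])
        if not stained or not unstained:
            raise ValueError("both pools must be non-empty")
        rng = np.random.default_rng(self.seed)
        self._build()
        policy = (self.policy or AugmentationPolicy()).strong()
        buf_x = InputBuffer(self.buffer_capacity, rng_seed=int(rng.integers(2 ** 31)))
        buf_y = InputBuffer(self.buffer_capacity, rng_seed=int(rng.integers(2 ** 31)))

        gen_params = list(self.g1_.parameters()) + list(self.g2_.parameters())
        d_params = list(self.dx_.parameters()) + list(self.dy_.parameters())
        c_params = list(self.c1_.parameters()) + list(self.c2_.parameters())
        opt_g = Adam(gen_params, lr=self.lr)
        opt_d = Adam(d_params, lr=self.lr)
        opt_c = Adam(c_params, lr=self.lr)

        self.log_ = []
        b = self.batch_size
        for step in range(self.steps):
            xs = [stained[i] for i in rng.choice(len(stained), b)]
            ys = [unstained[i] for i in rng.choice(len(unstained), b)]
            buf_x.push([augment(t, policy, rng) for t in xs])
            buf_y.push([augment(t, policy, rng) for t in ys])
            x = _to_batch(xs)
            yb = _to_batch(ys)

            with no_grad():
                fake_y_const = self.g1_(x)
                fake_x_const = self.g2_(yb)

            # critics (least-squares adversarial game, CycleGAN convention)
            ld_y, _ = L.adv_l2(self.dy_, None, yb, fake_y_const)
            ld_x, _ = L.adv_l2(self.dx_, None, x, fake_x_const)
            loss_d = ld_y + ld_x
            opt_d.zero_grad()
            backward(loss_d, d_params)
            opt_d.step()

            # domain-consistency nets on buffered same-domain pairs
            (y1,), (y2,) = buf_y.sample(min(b, len(buf_y)), 1), buf_y.sample(min(b, len(buf_y)), 1)
            (x1,), (x2,) = buf_x.sample(min(b, len(buf_x)), 1), buf_x.sample(min(b, len(buf_x)), 1)
            ty1, ty2 = _to_batch(y1), _to_batch(y2)
            tx1, tx2 = _to_batch(x1), _to_batch(x2)
            nc = min(len(y1), fake_y_const.shape[0])
            lc1, _ = L.domain_consistency_loss(self.c1_, fake_y_const[:nc], ty1[:nc], ty2[:nc], None)
            lc2, _ = L.domain_consistency_loss(self.c2_, fake_x_const[:nc], tx1[:nc], tx2[:nc], None)
            loss_c = lc1 + lc2
            opt_c.zero_grad()
            backward(loss_c, c_params)
            opt_c.step()

            # generators: adversarial + cycle + domain consistency
            fake_y = self.g1_(x)
            fake_x = self.g2_(yb)
            adv_g = Tensor(0.0)
            if self.lambda_adv > 0:
                adv_g = (((self.dy_(fake_y) - 1.0) ** 2.0).mean()
                         + ((self.dx_(fake_x) - 1.0) ** 2.0).mean())
            cyc = Tensor(0.0)
            if self.lambda_cyc > 0:
                cyc = ((self.g2_(fake_y) - x).abs().mean()
                       + (self.g1_(fake_x) - yb).abs().mean())
            dc = Tensor(0.0)
            if self.lambda_dc > 0:
                _, g1_dc = L.domain_consistency_loss(self.c1_, fake_y[:nc], ty1[:nc], ty2[:nc], None)
                _, g2_dc = L.domain_consistency_loss(self.c2_, fake_x[:nc], tx1[:nc], tx2[:nc], None)
                dc = g1_dc + g2_dc
            loss_g = self.lambda_adv * adv_g + self.lambda_cyc * cyc + self.lambda_dc * dc
            opt_g.zero_grad()
            backward(loss_g, gen_params)
            opt_g.step()

            entry = {
                "step": step,
                "loss_d": float(loss_d.item()),
                "loss_c": float(loss_c.item()),
                "loss_g": float(loss_g.item()),
                "fake_unstained_mean": float(fake_y.data.mean()),
                "fake_stained_mean": float(fake_x.data.mean()),
            }
            _finite_or_raise(entry, step)
            self.log_.append(entry)
        self.n_steps_ = self.steps
        return self

    def transform(self, X) -> list[ImageTile]:
        """Map stained tiles to generated unstained tiles (deterministic)."""
        check_is_fitted(self, "g1_")
        out = []
        for t in X:
            with no_grad():
                fy = self.g1_(_to_batch([t]))
            out.extend(_from_batch(fy, UNSTAINED, t.value_range))
        return out

    # -- checkpointing ---------------------------------------------------
    _NETS = ("g1_", "g2_", "dx_", "dy_", "c1_", "c2_")

    def to_checkpoint(self) -> Checkpoint:
        check_is_fitted(self, "g1_")
        state = {n: getattr(self, n).state_dict() for n in self._NETS}
        return Checkpoint("stage1", self.get_params(), state, self.n_steps_)

    @classmethod
    def from_checkpoint(cls, ckpt: Checkpoint) -> "Stage1Translator":
        if ckpt.kind != "stage1":
            raise ValueError(f"expected a stage1 checkpoint, got {ckpt.kind!r}")
        params = dict(ckpt.config)
        params.pop("policy", None)
        est = cls(**params)
        est._build()
        for n in cls._NETS:
            getattr(est, n).load_state_dict(ckpt.state[n])
        est.n_steps_ = ckpt.step
        est.log_ = []
        return est


class PairedStainer(BaseEstimator, TransformerMixin):
    """Paired unstained -> stained generator (stage 2; PFFN by default).

    ``fit`` accepts a list of :class:`PairedSample`; ``transform`` maps
    unstained tiles to virtually stained tiles. ``generator`` selects
    "pffn" or the "unet" ablation baseline; ``adv_variant`` selects the
    adversarial loss (wgan_gp | logistic_r1 | l2).
    """

    def __init__(self, steps=300, batch_size=2, lr=2e-4, critic_steps=1,
                 feature_width=32, critic_width=16, generator="pffn",
                 adv_variant="wgan_gp", lambda_gp=10.0, lambda_pix=100.0,
                 lambda_fm=10.0, gamma_r1=10.0, unet_depth=6, seed=0):
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.critic_steps = critic_steps
        self.feature_width = feature_width
        self.critic_width = critic_width
        self.generator = generator
        self.adv_variant = adv_variant
        self.lambda_gp = lambda_gp
        self.lambda_pix = lambda_pix
        self.lambda_fm = lambda_fm
        self.gamma_r1 = gamma_r1
        self.unet_depth = unet_depth
        self.seed = seed

    def _build(self, base_size: int):
        gcfg = net.NetworkConfig(feature_width=self.feature_width,
                                 base_width=self.feature_width,
                                 unet_depth=self.unet_depth,
                                 rng_seed=self.seed)
        if self.generator == "pffn":
            self.gen_ = net.build_pffn(gcfg, net.PyramidSpec.for_size(base_size))
        elif self.generator == "unet":
            self.gen_ = net.build_unet_baseline(gcfg)
        else:
            raise ValueError(f"unknown generator {self.generator!r}")
        dcfg = net.NetworkConfig(base_width=self.critic_width, conditional=True,
                                 rng_seed=self.seed + 1)
        self.critic_ = net.build_patch_critic(dcfg)
        self.base_size_ = base_size

    def fit(self, X, y=None):
        pairs = list(X)
        if not pairs:
            raise ValueError("need at least one training pair")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        weights = L.LossWeights(lambda_gp=self.lambda_gp, lambda_pix=self.lambda_pix,
                                lambda_fm=self.lambda_fm, gamma_r1=self.gamma_r1,
                                adv_variant=self.adv_variant)
        rng = np.random.default_rng(self.seed)
        base = pairs[0].stained.shape[0]
        self._build(base)
        g_params = list(self.gen_.parameters())
        d_params = list(self.critic_.parameters())
        opt_g = Adam(g_params, lr=self.lr)
        opt_d = Adam(d_params, lr=self.lr)

        self.log_ = []
        b = min(self.batch_size, len(pairs))
        for step in range(self.steps):
            loss_d_val = 0.0
            for _ in range(self.critic_steps):
                idx = rng.choice(len(pairs), b)
                x = _to_batch([pairs[i].unstained for i in idx])   # condition
                yt = _to_batch([pairs[i].stained for i in idx])    # target
                with no_grad():
                    fake = self.gen_(x)
                loss_d = self._critic_loss(weights, x, yt, fake, rng)
                opt_d.zero_grad()
                backward(loss_d, d_params)
                opt_d.step()
                loss_d_val = float(loss_d.item())

            idx = rng.choice(len(pairs), b)
            x = _to_batch([pairs[i].unstained for i in idx])
            yt = _to_batch([pairs[i].stained for i in idx])
            fake = self.gen_(x)
            adv_g = self._generator_adv(weights, x, yt, fake)
            pix = L.pixel_l1(fake, yt)
            if weights.lambda_fm > 0:
                _, feats_real = self.critic_(x, yt, return_features=True)
                _, feats_fake = self.critic_(x, fake, return_features=True)
                fm = L.feature_matching(feats_real, feats_fake)
            else:
                fm = Tensor(0.0)
            loss_g = L.total_loss(adv_g, pix, fm, weights)
            opt_g.zero_grad()
            backward(loss_g, g_params)
            opt_g.step()

            entry = {
                "step": step,
                "loss_d": loss_d_val,
                "loss_g": float(loss_g.item()),
                "l_pix": float(pix.item()),
                "l_fm": float(fm.item()),
                "l_adv": float(adv_g.item()),
            }
            _finite_or_raise(entry, step)
            self.log_.append(entry)
        self.n_steps_ = self.steps
        return self

    def _critic_loss(self, w: L.LossWeights, x, y_real, y_fake, rng):
        if w.adv_variant == "wgan_gp":
            ld, _ = L.adv_wgan_gp(self.critic_, x, y_real, y_fake, w.lambda_gp, rng)
        elif w.adv_variant == "logistic_r1":
            ld, _ = L.adv_logistic_r1(self.critic_, x, y_real, y_fake, w.gamma_r1)
        else:
            ld, _ = L.adv_l2(self.critic_, x, y_real, y_fake)
        return ld

    def _generator_adv(self, w: L.LossWeights, x, y_real, y_fake):
        if w.adv_variant == "wgan_gp":
            return -self.critic_(x, y_fake).mean()
        if w.adv_variant == "logistic_r1":
            return (-self.critic_(x, y_fake)).softplus().mean()
        return ((self.critic_(x, y_fake) - 1.0) ** 2.0).mean()

    def transform(self, X) -> list[ImageTile]:
        check_is_fitted(self, "gen_")
        out = []
        for t in X:
            if t.shape[0] != self.base_size_ or t.shape[1] != self.base_size_:
                raise ValueError(
                    f"tile size {t.shape[:2]} incompatible with model size "
                    f"{self.base_size_}")
            with no_grad():
                fy = self.gen_(_to_batch([t]))
            out.extend(_from_batch(fy, STAINED, t.value_range))
        return out

    def to_checkpoint(self) -> Checkpoint:
        check_is_fitted(self, "gen_")
        state = {"gen_": self.gen_.state_dict(), "critic_": self.critic_.state_dict()}
        cfg = dict(self.get_params())
        cfg["base_size"] = self.base_size_
        return Checkpoint("stage2", cfg, state, self.n_steps_)

    @classmethod
    def from_checkpoint(cls, ckpt: Checkpoint) -> "PairedStainer":
        if ckpt.kind != "stage2":
            raise ValueError(f"expected a stage2 checkpoint, got {ckpt.kind!r}")
        cfg = dict(ckpt.config)
        base = cfg.pop("base_size")
        est = cls(**cfg)
        est._build(base)
        est.gen_.load_state_dict(ckpt.state["gen_"])
        est.critic_.load_state_dict(ckpt.state["critic_"])
        est.n_steps_ = ckpt.step
        est.log_ = []
        return est


# ---------------------------------------------------------------------------
# functional wrappers


def train_stage1(stained_pool, unstained_pool, cfg: TrainConfig | None = None,
                 **params) -> Stage1Translator:
    cfg = cfg or TrainConfig(stage=1)
    defaults = dict(steps=cfg.steps, batch_size=cfg.batch_size, lr=cfg.lr,
                    buffer_capacity=cfg.buffer_capacity, seed=cfg.seed,
                    lambda_cyc=cfg.weights.lambda_cyc, lambda_dc=cfg.weights.lambda_dc)
    defaults.update(params)
    return Stage1Translator(**defaults).fit(stained_pool, unstained_pool)


def synthesize_pairs(model: Stage1Translator | Checkpoint, stained_pool,
                     labels=None) -> list[PairedSample]:
    """One generated unstained tile per stained tile, deterministically."""
    if isinstance(model, Checkpoint):
        model = Stage1Translator.from_checkpoint(model)
    check_is_fitted(model, "g1_")
    stained_pool = list(stained_pool)
    fakes = model.transform(stained_pool)
    labels = list(labels) if labels is not None else [0] * len(stained_pool)
    return [PairedSample(s, u, lab) for s, u, lab in zip(stained_pool, fakes, labels)]


def train_stage2(paired_set, cfg: TrainConfig | None = None, **params) -> PairedStainer:
    cfg = cfg or TrainConfig(stage=2)
    defaults = dict(steps=cfg.steps, batch_size=cfg.batch_size, lr=cfg.lr,
                    critic_steps=cfg.critic_steps, seed=cfg.seed,
                    adv_variant=cfg.weights.adv_variant,
                    lambda_gp=cfg.weights.lambda_gp,
                    lambda_pix=cfg.weights.lambda_pix,
                    lambda_fm=cfg.weights.lambda_fm,
                    gamma_r1=cfg.weights.gamma_r1)
    defaults.update(params)
    return PairedStainer(**defaults).fit(paired_set)


def stain(model: PairedStainer | Checkpoint, unstained: ImageTile) -> ImageTile:
    """Virtually stain one unstained tile."""
    if isinstance(model, Checkpoint):
        model = PairedStainer.from_checkpoint(model)
    return model.transform([unstained])[0]
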