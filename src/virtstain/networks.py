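"""Generator, critic and domain-consistency architectures.

Five builders cover the two training stages and their ablation baselines:

* ``build_resnet_generator`` — the Johnson-style residual generator used by
  CycleGAN (instance normalization after each convolution); the stage-1
  ablation baseline.
* ``build_sep_generator`` — the redesigned stage-1 generator: Xception-style
  depthwise-separable residual blocks with normalization removed from the
  body, and depthwise-separable up/down-sampling convolutions. The removal
  of per-channel normalization is what suppresses the "hole" artifacts the
  baseline produces on sparse target domains.
* ``build_patch_critic`` — a 70x70-receptive-field patchGAN critic,
  optionally conditional (condition and target concatenated on channels),
  exposing per-layer feature maps for the feature-matching loss.
* ``build_domain_consistency_net`` — the two-input same-domain judge: each
  input is downsampled three times with separable convolutions, features are
  fused and reduced by a 1x1-kernel stack to a single-channel map whose
  spatial size equals the patch critic's map for the same input size.
* ``build_pffn`` — the Parallel Feature Fusion Network: an average-pooling
  image pyramid feeds per-scale FromRGB modules (three parallel sampling
  branches fused to the network-wide feature width, 512 by default) and
  per-scale UNet extractors of depth 2/4/6 with an extra skip from each
  encoder level to the decoder level one step deeper; a coarse-to-fine
  fusion decoder merges the scales into the output image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor, concat
from .types import ImageTile

__all__ = [
    "NetworkConfig",
    "PyramidSpec",
    "avgpool_pyramid",
    "build_resnet_generator",
    "build_sep_generator",
    "build_patch_critic",
    "build_domain_consistency_net",
    "build_pffn",
    "build_unet_baseline",
    "critic_out_size",
]


@dataclass
class NetworkConfig:
    base_width: int = 64
    feature_width: int = 512
    in_channels: int = 3
    out_channels: int = 3
    use_instance_norm: bool = True
    n_res_blocks: int = 6
    unet_depth: int = 8
    conditional: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.base_width <= 0 or self.feature_width <= 0:
            raise ValueError("channel widths must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class PyramidSpec:
    """Average-pooling pyramid: step s yields size base_size / 2**(s-1)."""

    steps: list[int] = field(default_factory=lambda: [6, 5, 4, 3, 2, 1])
    base_size: int = 256

    def __post_init__(self):
        if not self.steps:
            raise ValueError("steps must be non-empty")
        if any(s < 1 for s in self.steps):
            raise ValueError("steps must be >= 1")
        if self.base_size % (2 ** (max(self.steps) - 1)) != 0:
            raise ValueError(
                f"base_size {self.base_size} not divisible by 2^{max(self.steps) - 1}")

    def sizes(self) -> list[int]:
        return [self.base_size // (2 ** (s - 1)) for s in self.steps]

    @classmethod
    def for_size(cls, base_size: int, max_size_factor: int = 32) -> "PyramidSpec":
        """Spec rescaled proportionally: scales down to base_size/32 (>= 8)."""
        n = 1
        while base_size % (2 ** n) == 0 and base_size // (2 ** n) >= 8 and 2 ** n <= max_size_factor:
            n += 1
        return cls(steps=list(range(n, 0, -1)), base_size=base_size)


def avgpool_pyramid(tile, spec: PyramidSpec):
    """Average-pool an image to every scale in ``spec``.

    Window equals stride (2**(s-1)), so the global mean is preserved at every
    scale. Accepts an ``ImageTile``, an HxWx3 array, or an (N, C, H, W)
    :class:`~virtstain.nn.Tensor`; returns the matching kind.
    """
    if isinstance(tile, Tensor):
        return [_pool_nchw_tensor(tile, 2 ** (s - 1)) for s in spec.steps]
    if isinstance(tile, ImageTile):
        arrs = [_pool_hwc(tile.data, 2 ** (s - 1)) for s in spec.steps]
        return [ImageTile(a, tile.domain, tile.value_range) for a in arrs]
    return [_pool_hwc(np.asarray(tile), 2 ** (s - 1)) for s in spec.steps]


def _pool_hwc(arr: np.ndarray, w: int) -> np.ndarray:
    H, W, C = arr.shape
    if H % w or W % w:
        raise ValueError(f"size {(H, W)} not divisible by pooling window {w}")
    return arr.reshape(H // w, w, W // w, w, C).mean(axis=(1, 3))


def _pool_nchw_tensor(x: Tensor, w: int) -> Tensor:
    if w == 1:
        return x
    return nn.AvgPool2d(w)(x)


def critic_out_size(size: int) -> int:
    """Analytic output size of the 70x70 patchGAN for a square input."""
    for _ in range(3):  # three stride-2 k4 p1 layers
        size = (size + 2 - 4) // 2 + 1
    for _ in range(2):  # two stride-1 k4 p1 layers
        size = size + 2 - 4 + 1
    return size


# ---------------------------------------------------------------------------
# stage-1 generators


class _ResBlock(nn.Module):
    def __init__(self, ch, use_in, rng):
        super().__init__()
        layers = [nn.Conv2d(ch, ch, 3, padding=1, rng=rng)]
        if use_in:
            layers.append(nn.InstanceNorm2d())
        layers += [nn.ReLU(), nn.Conv2d(ch, ch, 3, padding=1, rng=rng)]
        if use_in:
            layers.append(nn.InstanceNorm2d())
        self.body = nn.Sequential(*layers)

    def forward(self, x):
        return x + self.body(x)


class _XceptionBlock(nn.Module):
    """Separable-conv residual block, no normalization in the body."""

    def __init__(self, ch, rng):
        super().__init__()
        self.body = nn.Sequential(
            nn.SepConv2d(ch, ch, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.SepConv2d(ch, ch, 3, padding=1, rng=rng),
        )

    def forward(self, x):
        return x + self.body(x)


class _ImageGenerator(nn.Module):
    """Shared down / body / up topology; final tanh onto [-1, 1]."""

    def __init__(self, cfg: NetworkConfig, separable: bool):
        super().__init__()
        rng = cfg.rng()
        w = cfg.base_width
        conv = nn.SepConv2d if separable else nn.Conv2d
        use_in = cfg.use_instance_norm and not separable
        self.separable = separable
        self.in_channels = cfg.in_channels
        self.out_channels = cfg.out_channels

        def maybe_in(layers):
            if use_in:
                layers.append(nn.InstanceNorm2d())
            return layers

        enc = maybe_in([nn.Conv2d(cfg.in_channels, w, 7, padding=3, rng=rng)])
        enc.append(nn.ReLU())
        enc = enc + maybe_in([conv(w, 2 * w, 3, stride=2, padding=1, rng=rng)])
        enc.append(nn.ReLU())
        enc = enc + maybe_in([conv(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng)])
        enc.append(nn.ReLU())
        self.encoder = nn.Sequential(*enc)

        self.body = nn.Sequential(*[
            _XceptionBlock(4 * w, rng) if separable else _ResBlock(4 * w, use_in, rng)
            for _ in range(cfg.n_res_blocks)
        ])

        dec = [nn.Upsample2x()] + maybe_in([conv(4 * w, 2 * w, 3, padding=1, rng=rng)])
        dec.append(nn.ReLU())
        dec += [nn.Upsample2x()] + maybe_in([conv(2 * w, w, 3, padding=1, rng=rng)])
        dec.append(nn.ReLU())
        dec += [nn.Conv2d(w, cfg.out_channels, 7, padding=3, rng=rng), nn.Tanh()]
        self.decoder = nn.Sequential(*dec)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if H % 4 or W % 4:
            raise ValueError(f"spatial size {(H, W)} must be divisible by 4")
        return self.decoder(self.body(self.encoder(x)))


def build_resnet_generator(cfg: NetworkConfig) -> _ImageGenerator:
    """Johnson-style residual generator with instance normalization."""
    return _ImageGenerator(cfg, separable=False)


def build_sep_generator(cfg: NetworkConfig) -> _ImageGenerator:
    """Separable-convolution generator (Xception blocks, un-normalized body)."""
    return _ImageGenerator(cfg, separable=True)


# ---------------------------------------------------------------------------
# critics


class PatchCritic(nn.Module):
    """70x70 patchGAN. ``forward(..., return_features=True)`` exposes the
    activation after every convolutional layer for feature matching."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        rng = cfg.rng()
        w = cfg.base_width
        in_ch = cfg.in_channels * (2 if cfg.conditional else 1)
        self.conditional = cfg.conditional
        self.c1 = nn.Conv2d(in_ch, w, 4, stride=2, padding=1, rng=rng)
        self.c2 = nn.Conv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng)
        self.c3 = nn.Conv2d(2 * w, 4 * w, 4, stride=2, padding=1, rng=rng)
        self.c4 = nn.Conv2d(4 * w, 8 * w, 4, stride=1, padding=1, rng=rng)
        self.c5 = nn.Conv2d(8 * w, 1, 4, stride=1, padding=1, rng=rng)
        self.n_feature_layers = 5

    def forward(self, x: Tensor, y: Tensor | None = None, return_features: bool = False):
        if self.conditional:
            if y is None:
                raise ValueError("conditional critic needs (condition, target)")
            if x.shape != y.shape:
                raise ValueError("condition and target must share shape")
            h = concat([x, y], axis=1)
        else:
            h = x if y is None else y
        feats = []
        for conv in (self.c1, self.c2, self.c3, self.c4):
            h = conv(h).leaky_relu(0.2)
            feats.append(h)
        h = self.c5(h)
        feats.append(h)
        return (h, feats) if return_features else h


def build_patch_critic(cfg: NetworkConfig) -> PatchCritic:
    return PatchCritic(cfg)


class DomainConsistencyNet(nn.Module):
    """Two-image same-domain judge (the stage-1 auxiliary discriminator).

    A shared separable-conv encoder downsamples each input three times;
    the two feature stacks are concatenated and reduced by 1x1 convolutions
    to one channel. Since 1x1 kernels cannot change the spatial size, the
    map is center-cropped to the patch critic's analytic output size so the
    two discriminators share an output contract.
    """

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        rng = cfg.rng()
        w = cfg.base_width
        self.encoder = nn.Sequential(
            nn.SepConv2d(cfg.in_channels, w, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.SepConv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.SepConv2d(2 * w, 4 * w, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
        )
        self.fuse = nn.Sequential(
            nn.Conv2d(8 * w, 4 * w, 1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(4 * w, 2 * w, 1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(2 * w, 1, 1, rng=rng),
        )

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape != b.shape:
            raise ValueError("domain net inputs must share shape")
        h = self.fuse(concat([self.encoder(a), self.encoder(b)], axis=1))
        target = critic_out_size(a.shape[-1])
        cur = h.shape[-1]
        if cur < target:
            raise ValueError(f"input too small: map {cur} < critic map {target}")
        off = (cur - target) // 2
        return h[:, :, off:off + target, off:off + target]


def build_domain_consistency_net(cfg: NetworkConfig) -> DomainConsistencyNet:
    return DomainConsistencyNet(cfg)


# ---------------------------------------------------------------------------
# PFFN


class _FromRGB(nn.Module):
    """Lift a 3-channel image to the network feature width via three
    parallel sampling branches (stride-2 conv, avg-pool+conv, max-pool+conv),
    concatenated and fused by a 1x1 convolution. Output is at half the
    input resolution."""

    def __init__(self, in_ch: int, fw: int, rng):
        super().__init__()
        b = max(fw // 4, 4)
        self.stride_branch = nn.Conv2d(in_ch, b, 3, stride=2, padding=1, rng=rng)
        self.avg_branch = nn.Sequential(nn.AvgPool2d(2),
                                        nn.Conv2d(in_ch, b, 3, padding=1, rng=rng))
        self.max_branch = nn.Sequential(nn.MaxPool2d(2),
                                        nn.Conv2d(in_ch, b, 3, padding=1, rng=rng))
        self.fuse = nn.Conv2d(3 * b, fw, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = concat([self.stride_branch(x), self.avg_branch(x), self.max_branch(x)], axis=1)
        return self.fuse(h).leaky_relu(0.2)


class _ConvBlock(nn.Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, use_in=True):
        super().__init__()
        layers = [nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)]
        if use_in:
            layers.append(nn.InstanceNorm2d())
        layers.append(nn.LeakyReLU(0.2))
        self.body = nn.Sequential(*layers)

    def forward(self, x):
        return self.body(x)


class UNetExtractor(nn.Module):
    """Depth-d UNet with same-level skips plus an extra skip from each
    encoder level to the decoder level one step deeper (a pruned UNet3+
    pattern). ``n_levels`` counts the downsampling stages (the feature
    sampling depth)."""

    def __init__(self, fw: int, depth: int, rng, use_in=True):
        super().__init__()
        self.n_levels = depth
        self.downs = nn.Sequential(*[
            _ConvBlock(fw, fw, rng, stride=2, use_in=use_in) for _ in range(depth)
        ])
        self.dec_fuse = []
        self.dec_conv = []
        for j in range(depth):
            # decoder level j receives: upsampled deeper feature, same-level
            # encoder skip, and (for j >= 1) the pooled skip from level j-1
            n_in = fw * (3 if j >= 1 else 2)
            fuse = nn.Conv2d(n_in, fw, 1, rng=rng)
            conv = _ConvBlock(fw, fw, rng, use_in=use_in)
            setattr(self, f"dfuse{j}", fuse)
            setattr(self, f"dconv{j}", conv)
            self.dec_fuse.append(fuse)
            self.dec_conv.append(conv)
        self.pool = nn.AvgPool2d(2)

    def forward(self, x: Tensor) -> Tensor:
        enc = [x]  # enc[l] at size S / 2**l
        h = x
        for down in self.downs.items:
            h = down(h)
            enc.append(h)
        d = self.n_levels
        h = enc[d]
        for j in range(d - 1, -1, -1):
            parts = [h.upsample2x(), enc[j]]
            if j >= 1:
                parts.append(self.pool(enc[j - 1]))
            h = self.dec_conv[j](self.dec_fuse[j](concat(parts, axis=1)))
        return h


def _subnet_depth(size: int) -> int:
    """Scale -> extractor depth: 8/16 -> 2, 32/64 -> 4, 128/256 -> 6."""
    if size <= 16:
        return 2
    if size <= 64:
        return 4
    return 6


class PFFN(nn.Module):
    """Parallel Feature Fusion Network generator."""

    def __init__(self, cfg: NetworkConfig, spec: PyramidSpec):
        super().__init__()
        rng = cfg.rng()
        fw = cfg.feature_width
        self.spec = spec
        self.in_channels = cfg.in_channels
        self.out_channels = cfg.out_channels
        sizes = sorted(spec.sizes())
        if sizes[0] < 8:
            raise ValueError("smallest pyramid scale must be >= 8")
        self.scale_sizes = sizes
        self.from_rgb = []
        self.extractors = []
        for i, s in enumerate(sizes):
            depth = _subnet_depth(s)
            if (s // 2) < 2 ** depth:
                raise ValueError(f"scale {s} incompatible with UNet depth {depth}")
            fr = _FromRGB(cfg.in_channels, fw, rng)
            ex = UNetExtractor(fw, depth, rng, use_in=cfg.use_instance_norm)
            setattr(self, f"fromrgb{i}", fr)
            setattr(self, f"extract{i}", ex)
            self.from_rgb.append(fr)
            self.extractors.append(ex)
        # fusion decoder: coarse-to-fine; feature maps live at size/2
        self.fuse_convs = []
        self.ref_convs = []
        for i in range(1, len(sizes)):
            fc = nn.Conv2d(2 * fw, fw, 1, rng=rng)
            rc = _ConvBlock(fw, fw, rng, use_in=cfg.use_instance_norm)
            setattr(self, f"ffuse{i}", fc)
            setattr(self, f"frefine{i}", rc)
            self.fuse_convs.append(fc)
            self.ref_convs.append(rc)
        self.head = nn.Conv2d(fw, cfg.out_channels, 3, padding=1, rng=rng)

    @property
    def n_levels_per_scale(self):
        return {s: ex.n_levels for s, ex in zip(self.scale_sizes, self.extractors)}

    def forward(self, x: Tensor, return_scale_features: bool = False):
        N, C, H, W = x.shape
        if H != self.spec.base_size or W != self.spec.base_size:
            raise ValueError(
                f"input {(H, W)} incompatible with pyramid base {self.spec.base_size}")
        pyramid = {t.shape[-1]: t for t in avgpool_pyramid(x, self.spec)}
        feats = []
        for s, fr, ex in zip(self.scale_sizes, self.from_rgb, self.extractors):
            feats.append(ex(fr(pyramid[s])))  # at size s/2
        h = feats[0]
        for i in range(1, len(feats)):
            h = self.fuse_convs[i - 1](concat([h.upsample2x(), feats[i]], axis=1))
            h = self.ref_convs[i - 1](h)
        out = self.head(h.upsample2x()).tanh()
        if return_scale_features:
            return out, {s: f for s, f in zip(self.scale_sizes, feats)}
        return out


def build_pffn(cfg: NetworkConfig, spec: PyramidSpec | None = None) -> PFFN:
    return PFFN(cfg, spec or PyramidSpec())


class UNetBaseline(nn.Module):
    """Classic encoder-decoder UNet with same-level skips (ablation
    baseline); ``n_levels`` downsampling stages, 8 by default."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        rng = cfg.rng()
        w = cfg.base_width
        self.n_levels = cfg.unet_depth
        self.in_channels = cfg.in_channels
        self.out_channels = cfg.out_channels
        self.stem = _ConvBlock(cfg.in_channels, w, rng, use_in=False)
        self.downs = nn.Sequential(*[
            _ConvBlock(w, w, rng, stride=2, use_in=cfg.use_instance_norm)
            for _ in range(self.n_levels)
        ])
        self.dec_fuse = []
        self.dec_conv = []
        for j in range(self.n_levels):
            fc = nn.Conv2d(2 * w, w, 1, rng=rng)
            cc = _ConvBlock(w, w, rng, use_in=cfg.use_instance_norm)
            setattr(self, f"ufuse{j}", fc)
            setattr(self, f"uconv{j}", cc)
            self.dec_fuse.append(fc)
            self.dec_conv.append(cc)
        self.head = nn.Conv2d(w, cfg.out_channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if H % (2 ** self.n_levels) or W % (2 ** self.n_levels):
            raise ValueError(
                f"spatial size {(H, W)} must be divisible by 2^{self.n_levels}")
        h = self.stem(x)
        enc = [h]
        for down in self.downs.items:
            h = down(h)
            enc.append(h)
        for j in range(self.n_levels - 1, -1, -1):
            h = self.dec_conv[j](self.dec_fuse[j](concat([h.upsample2x(), enc[j]], axis=1)))
        return self.head(h).tanh()


def build_unet_baseline(cfg: NetworkConfig) -> UNetBaseline:
    return UNetBaseline(cfg)
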