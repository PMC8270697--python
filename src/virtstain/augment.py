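"""Stage-1 data augmentation and the input buffer.

The augmentation chain follows the order: random jitter (translation),
horizontal/vertical flips, jitter rotation (upscale by ``zoom``, rotate a
small random angle, center-crop back to the original size), then elastic
deformation. Identity settings short-circuit every step, so the identity
policy is a bit-exact no-op.

The input buffer is a bounded FIFO pool of heavily augmented real tiles;
during training the domain-consistency game draws same-domain batches from
it at random.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .types import ImageTile

__all__ = ["AugmentationPolicy", "augment", "elastic_warp", "InputBuffer"]


@dataclass
class AugmentationPolicy:
    jitter_px: int = 0
    p_hflip: float = 0.0
    p_vflip: float = 0.0
    rot_max_deg: float = 0.0
    zoom: float = 1.0
    elastic_alpha: float = 0.0
    elastic_sigma: float = 8.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        for p in (self.p_hflip, self.p_vflip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.rot_max_deg < 0:
            raise ValueError("rot_max_deg must be >= 0")
        if self.zoom < 1.0:
            raise ValueError("zoom must be >= 1")
        if self.elastic_alpha < 0 or self.elastic_sigma < 0:
            raise ValueError("elastic parameters must be >= 0")

    def strong(self) -> "AugmentationPolicy":
        """The heavy-augmentation variant used to fill the input buffer."""
        return replace(self, jitter_px=max(self.jitter_px, 4), p_hflip=0.5,
                       p_vflip=0.5, rot_max_deg=max(self.rot_max_deg, 10.0),
                       zoom=max(self.zoom, 1.1), elastic_alpha=max(self.elastic_alpha, 4.0))


def augment(tile: ImageTile, policy: AugmentationPolicy,
            rng: np.random.Generator | None = None) -> ImageTile:
    """Apply the augmentation chain; preserves shape and value range."""
    h, w, _ = tile.shape
    if h < 8 or w < 8:
        raise ValueError("tile must be at least 8x8")
    rng = rng if rng is not None else np.random.default_rng(policy.rng_seed)
    img = tile.data

    if policy.jitter_px > 0:
        dy = int(rng.integers(-policy.jitter_px, policy.jitter_px + 1))
        dx = int(rng.integers(-policy.jitter_px, policy.jitter_px + 1))
        if dy or dx:
            img = ndimage.shift(img, (dy, dx, 0), order=1, mode="reflect")

    if policy.p_hflip > 0 and rng.random() < policy.p_hflip:
        img = img[:, ::-1]
    if policy.p_vflip > 0 and rng.random() < policy.p_vflip:
        img = img[::-1]

    if policy.zoom > 1.0 or policy.rot_max_deg > 0:
        # jitter rotation: interpolate-and-zoom, rotate a small angle, crop back
        if policy.zoom > 1.0:
            img = ndimage.zoom(img, (policy.zoom, policy.zoom, 1.0), order=1,
                               mode="reflect", grid_mode=True)
        theta = float(rng.uniform(-policy.rot_max_deg, policy.rot_max_deg))
        if policy.rot_max_deg > 0 and theta != 0.0:
            img = ndimage.rotate(img, theta, axes=(0, 1), reshape=False,
                                 order=1, mode="reflect")
        img = _center_crop(img, h, w)

    if policy.elastic_alpha > 0:
        img = elastic_warp(img, policy.elastic_alpha, policy.elastic_sigma, rng)

    lo, hi = tile.value_range
    if img is not tile.data:
        img = np.clip(np.ascontiguousarray(img), lo, hi)
    return ImageTile(img, tile.domain, tile.value_range)


def _center_crop(img: np.ndarray, h: int, w: int) -> np.ndarray:
    H, W = img.shape[:2]
    y0 = (H - h) // 2
    x0 = (W - w) // 2
    return img[y0:y0 + h, x0:x0 + w]


def elastic_warp(img: np.ndarray, alpha: float, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Elastic deformation: Gaussian-smoothed uniform displacement field
    scaled by ``alpha``, sampled with bilinear interpolation and reflected
    borders (the standard recipe for microscopy augmentation)."""
    h, w = img.shape[:2]
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, size=(h, w)), sigma, mode="reflect") * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, size=(h, w)), sigma, mode="reflect") * alpha
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = ndimage.map_coordinates(img[:, :, c], coords, order=1, mode="reflect")
    return out


class InputBuffer:
    """Bounded FIFO pool of tiles with seeded random batch draws."""

    def __init__(self, capacity: int, rng_seed: int = 0):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._items: list[ImageTile] = []
        self._rng = np.random.default_rng(rng_seed)

    def __len__(self):
        return len(self._items)

    def push(self, tiles) -> "InputBuffer":
        """Append tiles, evicting oldest-first beyond capacity."""
        for t in tiles:
            self._items.append(t)
        if len(self._items) > self.capacity:
            del self._items[: len(self._items) - self.capacity]
        return self

    def dump(self) -> list[ImageTile]:
        return list(self._items)

    def sample(self, batch: int, n_batches: int = 1) -> list[list[ImageTile]]:
        """Draw ``n_batches`` independent batches, each without replacement."""
        if batch > len(self._items):
            raise ValueError(
                f"cannot draw batch of {batch} from buffer of {len(self._items)}")
        out = []
        for _ in range(n_batches):
            idx = self._rng.choice(len(self._items), size=batch, replace=False)
            out.append([self._items[i] for i in idx])
        return out
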