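"""Synthetic histology tiles for paired and unpaired stain translation.

Generates cell geometries (elliptical nuclei inside a cytoplasm halo) and
renders each geometry in two modalities that mimic the statistical structure
of the real problem: a stained render with an H&E-like palette (purple
nuclei, pink cytoplasm, bright background) and an unstained render that is
autofluorescence-like — intensity-dominated, near-monochrome, with bright
cytoplasm on a dark background and quenched nuclei. The same geometry
rendered in both modalities yields a perfectly aligned pair, which is what
the paired stage of the method trains on.

The tumor class label (K classes, default 4) modulates the stain palette
hue slightly, giving a downstream classifier a learnable but non-trivial
signal, emulating tumor-type structure in real slides.

Sampling recipe (fixed, documented for independent re-implementation):
given ``rng = numpy.random.default_rng(seed)``, draw in order

1. ``n = rng.poisson(density * width * height / 1e4)``
2. per nucleus i (i = 0..n-1): ``cx = rng.uniform(0, width)``,
   ``cy = rng.uniform(0, height)``, ``a = rng.uniform(4, 9)``,
   ``b = rng.uniform(3, 7)``, ``theta = rng.uniform(0, pi)``
3. ``tumor_class = rng.integers(0, n_classes)``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import STAINED, UNSTAINED, ImageTile

__all__ = [
    "CellGeometry",
    "RenderParams",
    "generate_geometry",
    "foreground_mask",
    "render_stained",
    "render_unstained",
    "make_dataset",
    "load_manifest",
]

CYTO_SCALE = 2.2  # cytoplasm halo = nucleus ellipse scaled by this factor


@dataclass
class CellGeometry:
    """Nuclei ellipses plus a derived cytoplasm mask on a fixed canvas."""

    width: int
    height: int
    nuclei: list[tuple[float, float, float, float, float]]  # (cx, cy, a, b, theta)
    cytoplasm_mask: np.ndarray
    tumor_class: int
    seed: int

    def __post_init__(self):
        for cx, cy, _, _, _ in self.nuclei:
            if not (0 <= cx <= self.width and 0 <= cy <= self.height):
                raise ValueError("nucleus center outside canvas")


@dataclass
class RenderParams:
    """Appearance parameters for both render modalities.

    Colors are RGB triples in ``value_range`` units. ``fluor_gain`` scales
    the autofluorescence foreground intensity; ``noise_sd`` is the additive
    Gaussian noise level (same units).
    """

    nucleus_color: tuple[float, float, float] = (0.35, 0.22, 0.55)
    cytoplasm_color: tuple[float, float, float] = (0.91, 0.65, 0.76)
    background_color: tuple[float, float, float] = (0.95, 0.93, 0.96)
    fluor_gain: float = 0.75
    noise_sd: float = 0.02
    value_range: tuple[float, float] = (0.0, 1.0)
    class_hue_shift: float = 0.06
    noise_seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy lo < hi")


def generate_geometry(width: int, height: int, density: float, n_classes: int,
                      rng_seed: int) -> CellGeometry:
    """Draw a seeded random cell geometry.

    ``density`` is expected nuclei per 10^4 px^2; the count is Poisson, the
    centers uniform on the canvas, so all centers lie inside by construction.
    """
    if width < 8 or height < 8:
        raise ValueError("canvas must be at least 8x8")
    if density < 0:
        raise ValueError("density must be >= 0")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = int(rng.poisson(density * width * height / 1e4))
    nuclei = []
    for _ in range(n):
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        a = rng.uniform(4.0, 9.0)
        b = rng.uniform(3.0, 7.0)
        theta = rng.uniform(0, np.pi)
        nuclei.append((cx, cy, a, b, theta))
    tumor_class = int(rng.integers(0, n_classes))
    cyto = _ellipse_mask(width, height, nuclei, CYTO_SCALE)
    return CellGeometry(width, height, nuclei, cyto, tumor_class, rng_seed)


def _ellipse_mask(width: int, height: int, nuclei, scale: float) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    for cx, cy, a, b, theta in nuclei:
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask |= (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0
    return mask


def nucleus_mask(geom: CellGeometry) -> np.ndarray:
    return _ellipse_mask(geom.width, geom.height, geom.nuclei, 1.0)


def foreground_mask(geom: CellGeometry) -> np.ndarray:
    """Union of nucleus and cytoplasm regions; identical across modalities."""
    return geom.cytoplasm_mask | nucleus_mask(geom)


def _class_palette(params: RenderParams, k: int):
    """Tint the whole stain palette slightly by tumor class (a global
    tumor-type-dependent stain cast), so every pixel carries class signal."""
    ang = 2.0 * np.pi * k / 4.0
    shift = params.class_hue_shift * np.array([np.cos(ang), np.sin(ang), -np.cos(ang)])
    return (np.array(params.nucleus_color) + shift,
            np.array(params.cytoplasm_color) + shift,
            np.array(params.background_color) + shift)


def render_stained(geom: CellGeometry, params: RenderParams) -> ImageTile:
    """H&E-like render: colored nuclei/cytoplasm on a bright background."""
    nuc_c, cyt_c, bg_c = _class_palette(params, geom.tumor_class)
    img = np.empty((geom.height, geom.width, 3))
    img[:] = bg_c
    img[geom.cytoplasm_mask] = cyt_c
    img[nucleus_mask(geom)] = nuc_c
    return _finish(img, params, STAINED)


def render_unstained(geom: CellGeometry, params: RenderParams) -> ImageTile:
    """Autofluorescence-like render: near-monochrome intensity image.

    Channels are exact scalar multiples of one intensity field, so the
    inter-channel correlation is 1.0 before noise. Cytoplasm fluoresces at
    ``fluor_gain``, nuclei quench to 40% of that, background stays dark.
    """
    lo, hi = params.value_range
    span = hi - lo
    intensity = np.full((geom.height, geom.width), lo + 0.06 * span)
    intensity[geom.cytoplasm_mask] = lo + params.fluor_gain * span
    intensity[nucleus_mask(geom)] = lo + 0.4 * params.fluor_gain * span
    tint = np.array([0.92, 1.0, 0.88])  # faint green cast typical of NADH/FAD emission
    img = intensity[:, :, None] * tint[None, None, :]
    return _finish(img, params, UNSTAINED)


def _finish(img: np.ndarray, params: RenderParams, domain: str) -> ImageTile:
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.noise_seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    lo, hi = params.value_range
    return ImageTile(np.clip(img, lo, hi), domain, params.value_range)


@dataclass
class DatasetSpec:
    """Knobs for :func:`make_dataset`; defaults mirror the study regime
    (400 stained vs 80 unstained tiles, unpaired)."""

    n_stained: int = 400
    n_unstained: int = 80
    paired: bool = False
    tile: int = 256
    density: float = 5.0
    n_classes: int = 4
    noise_sd: float = 0.02
    render: RenderParams = field(default_factory=RenderParams)


def make_dataset(out_dir, n_stained: int = 400, n_unstained: int = 80,
                 paired: bool = False, tile: int = 256, seed: int = 0,
                 density: float = 5.0, n_classes: int = 4,
                 render: RenderParams | None = None) -> dict:
    """Write PNG tiles plus a JSON manifest; return the manifest dict.

    Unpaired mode draws disjoint geometry seeds per domain; paired mode
    reuses one geometry per (stained, unstained) pair so foreground masks
    coincide pixel-for-pixel.
    """
    from . import io as vio

    if n_stained < 0 or n_unstained < 0:
        raise ValueError("counts must be >= 0")
    if paired and n_stained != n_unstained:
        raise ValueError("paired datasets require n_stained == n_unstained")
    out_dir = Path(out_dir)
    render = render or RenderParams()
    rng = np.random.default_rng(seed)

    items = []

    def _emit(name: str, geom: CellGeometry, domain: str, pair_id=None):
        params = RenderParams(**{**render.__dict__,
                                 "noise_seed": int(rng.integers(0, 2 ** 31 - 1))})
        tile_img = (render_stained if domain == STAINED else render_unstained)(geom, params)
        rel = f"{domain}/{name}.png"
        vio.write_tile(tile_img, out_dir / rel)
        rec = {"path": rel, "domain": domain, "class": geom.tumor_class, "seed": geom.seed}
        if pair_id is not None:
            rec["pair_id"] = pair_id
        items.append(rec)

    if paired:
        for i in range(n_stained):
            gseed = int(rng.integers(0, 2 ** 31 - 1))
            geom = generate_geometry(tile, tile, density, n_classes, gseed)
            _emit(f"pair{i:05d}", geom, STAINED, pair_id=i)
            _emit(f"pair{i:05d}", geom, UNSTAINED, pair_id=i)
    else:
        for i in range(n_stained):
            gseed = int(rng.integers(0, 2 ** 31 - 1))
            geom = generate_geometry(tile, tile, density, n_classes, gseed)
            _emit(f"tile{i:05d}", geom, STAINED)
        for i in range(n_unstained):
            gseed = int(rng.integers(0, 2 ** 31 - 1))
            geom = generate_geometry(tile, tile, density, n_classes, gseed)
            _emit(f"tile{i:05d}", geom, UNSTAINED)

    manifest = {
        "schema_version": 1,
        "tile": tile,
        "paired": paired,
        "n_classes": n_classes,
        "seed": seed,
        "items": items,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        return json.load(fh)


def geometry_tiles(n: int, tile: int, seed: int, density: float = 5.0,
                   n_classes: int = 4, noise_sd: float = 0.02,
                   domain: str = STAINED) -> tuple[list[ImageTile], list[int]]:
    """In-memory convenience: n rendered tiles plus their class labels."""
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    for _ in range(n):
        gseed = int(rng.integers(0, 2 ** 31 - 1))
        geom = generate_geometry(tile, tile, density, n_classes, gseed)
        params = RenderParams(noise_sd=noise_sd,
                              noise_seed=int(rng.integers(0, 2 ** 31 - 1)))
        render = render_stained if domain == STAINED else render_unstained
        tiles.append(render(geom, params))
        labels.append(geom.tumor_class)
    return tiles, labels


def paired_tiles(n: int, tile: int, seed: int, density: float = 5.0,
                 n_classes: int = 4, noise_sd: float = 0.02):
    """In-memory paired samples sharing geometry."""
    from .types import PairedSample

    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        gseed = int(rng.integers(0, 2 ** 31 - 1))
        geom = generate_geometry(tile, tile, density, n_classes, gseed)
        ps = RenderParams(noise_sd=noise_sd,
                          noise_seed=int(rng.integers(0, 2 ** 31 - 1)))
        pu = RenderParams(noise_sd=noise_sd,
                          noise_seed=int(rng.integers(0, 2 ** 31 - 1)))
        pairs.append(PairedSample(render_stained(geom, ps),
                                  render_unstained(geom, pu),
                                  geom.tumor_class))
    return pairs
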