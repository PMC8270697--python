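"""Tile and report I/O.

Images are exchanged as 8-bit PNG or 8/16-bit TIFF. On read, pixel values
are affinely mapped to the model scale [-1, 1] (0 -> -1, full-scale -> +1);
on write, a tile's declared value range is mapped back to the container bit
depth. Directory listings are lexicographic so runs are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import STAINED, UNSTAINED, ImageTile, MetricReport

__all__ = ["read_tiles", "read_tile", "write_tile", "write_report", "read_report"]

_IMG_SUFFIXES = (".png", ".tif", ".tiff")


def read_tile(path, domain: str | None = None) -> ImageTile:
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - annotate offending file
        raise IOError(f"cannot read image file: {path}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[:, :, :3]
    full = 65535.0 if arr.dtype == np.uint16 else 255.0
    data = arr.astype(np.float64) / full * 2.0 - 1.0
    if domain is None:
        domain = UNSTAINED if "unstained" in str(path) else STAINED
    return ImageTile(data, domain, value_range=(-1.0, 1.0))


def read_tiles(source, domain: str | None = None, strict: bool = True) -> list[ImageTile]:
    """Read all tiles from a directory or a dataset manifest.

    ``strict`` requires all tiles to share one shape.
    """
    source = Path(source)
    tiles: list[ImageTile] = []
    manifest_path = source if (source.is_file() and source.suffix == ".json") else source / "manifest.json"
    if manifest_path.exists():
        root = manifest_path.parent
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        for item in manifest["items"]:
            tiles.append(read_tile(root / item["path"], item["domain"]))
    elif source.is_dir():
        paths = sorted(p for p in source.rglob("*") if p.suffix.lower() in _IMG_SUFFIXES)
        if not paths:
            raise IOError(f"no image files under {source}")
        tiles = [read_tile(p, domain) for p in paths]
    else:
        tiles = [read_tile(source, domain)]
    if strict and len({t.shape for t in tiles}) > 1:
        raise ValueError("tiles have mixed sizes (strict mode)")
    return tiles


def write_tile(tile: ImageTile, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lo, hi = tile.value_range
    arr = np.clip((tile.data - lo) / (hi - lo), 0.0, 1.0)
    u8 = np.round(arr * 255.0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        iio.imwrite(path, u8)


def write_report(report, path) -> None:
    """Write a MetricReport as JSON or a training log (list of dicts) as JSONL."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if isinstance(report, MetricReport):
            with open(path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=1)
        elif isinstance(report, list):
            with open(path, "w") as fh:
                for entry in report:
                    fh.write(json.dumps({"schema_version": 1, **entry}) + "\n")
        else:
            with open(path, "w") as fh:
                json.dump({"schema_version": 1, **dict(report)}, fh, indent=1)
    except OSError as exc:
        raise IOError(f"cannot write report to {path}") from exc


def read_report(path):
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    if path.suffix == ".jsonl":
        return [json.loads(line) for line in text.splitlines() if line.strip()]
    return json.loads(text)
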