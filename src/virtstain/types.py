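"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAINED = "stained"
UNSTAINED = "unstained"


@dataclass
class ImageTile:
    """An H x W x 3 raster in a declared value range with a domain tag.

    ``domain`` is ``"stained"`` (H&E-like brightfield appearance) or
    ``"unstained"`` (autofluorescence-like, intensity-dominated).
    """

    data: np.ndarray
    domain: str
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"tile must be HxWx3, got shape {self.data.shape}")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy lo < hi")
        if self.domain not in (STAINED, UNSTAINED):
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def shape(self):
        return self.data.shape

    def to_unit(self) -> np.ndarray:
        """Map into [-1, 1], the model-side convention."""
        lo, hi = self.value_range
        return (self.data - lo) / (hi - lo) * 2.0 - 1.0

    @classmethod
    def from_unit(cls, arr: np.ndarray, domain: str,
                  value_range: tuple[float, float] = (0.0, 1.0)) -> "ImageTile":
        lo, hi = value_range
        return cls((np.clip(arr, -1.0, 1.0) + 1.0) / 2.0 * (hi - lo) + lo, domain, value_range)

    def clipped(self) -> "ImageTile":
        lo, hi = self.value_range
        return ImageTile(np.clip(self.data, lo, hi), self.domain, self.value_range)


@dataclass
class PairedSample:
    """Spatially aligned (stained, unstained) tiles sharing cell geometry."""

    stained: ImageTile
    unstained: ImageTile
    label: int = 0

    def __post_init__(self):
        if self.stained.shape != self.unstained.shape:
            raise ValueError("paired tiles must share shape")


@dataclass
class MetricReport:
    """FID / IS / MS summary with provenance metadata."""

    fid: float
    is_score: float
    ms: float
    n_real: int
    n_fake: int
    embedder: str
    is_gap: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "fid": self.fid,
            "is_score": self.is_score,
            "ms": self.ms,
            "is_gap": self.is_gap,
            "n_real": self.n_real,
            "n_fake": self.n_fake,
            "embedder": self.embedder,
            **({"extras": self.extras} if self.extras else {}),
        }
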