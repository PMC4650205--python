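"""Core data containers shared across the pipeline.

The central object is :class:`DigitizedCrossSection` — an ordered planar
point chain in millimetres describing one transverse leaf section, with an
optional midrib landmark. Coordinates follow the mathematical convention:
y increases toward the adaxial (upper) leaf surface, and points run from
one strip edge to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .errors import InvalidSpec


@dataclass
class SectionImage:
    """A single-section micro-photograph.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensity grid; the leaf strip is the bright foreground on a dark
        background (the acquisition protocol deliberately overexposes the
        strip).
    mm_per_px : float
        Physical pixel size, millimetres per pixel.
    adaxial_up : bool
        Whether the adaxial surface faces the top of the image. Digitised
        coordinates are emitted y-up with the adaxial side at larger y.
    stroke_mask : ndarray of bool, optional
        For synthetic renders only: the exact rasterised stroke, kept so
        tests can compare a recovered binary mask against ground truth.
    """

    pixels: np.ndarray
    mm_per_px: float
    adaxial_up: bool = True
    stroke_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class BinaryMask:
    """Foreground mask of a section image (same shape as the source)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SkeletonChain:
    """Ordered 8-connected simple pixel path along the strip midline.

    ``pixels`` is an (m, 2) integer array of (row, col) positions;
    consecutive entries are 8-neighbours and no pixel repeats.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)

    def __len__(self) -> int:
        return len(self.pixels)

    def path_length(self) -> float:
        """Euclidean path length in pixels."""
        d = np.diff(self.pixels.astype(float), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class DigitizedCrossSection:
    """Ordered, scaled point chain for one leaf strip cross-section.

    ``points`` is an (n, 2) float array of (x, y) in mm, y-up with the
    adaxial surface toward +y. ``midrib_index`` locates the midrib landmark
    within the chain, if recorded. ``meta`` carries experiment annotations
    (genotype, rolling_group, psi_mpa, replicate, ...).
    """

    points: np.ndarray
    midrib_index: Optional[int] = None
    mm_per_px: Optional[float] = None
    adaxial_up: bool = True
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidSpec("points must be an (n, 2) array")
        if len(self.points) < 5:
            raise InvalidSpec("a cross-section needs at least 5 points")
        if not np.all(np.isfinite(self.points)):
            raise InvalidSpec("coordinates must be finite")
        if self.midrib_index is not None and not (
            0 <= self.midrib_index < len(self.points)
        ):
            raise InvalidSpec("midrib_index out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]
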