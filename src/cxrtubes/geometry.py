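"""Coordinate conventions and metric distances between image points.

Pixel coordinates are 0-based with the origin at the top-left corner of the
radiograph; ``x`` increases rightward (columns) and ``y`` increases downward
(rows).  "Above" in the anatomical sense (cranial) therefore means *smaller*
``y``.  All physical distances are in millimetres and are obtained from the
pixel spacing carried by :class:`ImageMeta`; anisotropic spacing (different
row/column pitch) is supported throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional


class SpacingError(ValueError):
    """Pixel spacing is missing or invalid for an image.

    Tube-position rules are denominated in centimetres, so a radiograph
    without a usable mm-per-pixel scale cannot be assessed.
    """


@dataclass(frozen=True)
class ImageMeta:
    """Size and physical scale of one radiograph.

    Parameters
    ----------
    width, height : int
        Image size in pixels.
    spacing_row : float
        Vertical pixel pitch in mm per pixel (row direction, i.e. ``y``).
    spacing_col : float, optional
        Horizontal pixel pitch in mm per pixel.  When omitted the row
        spacing is used for both axes (isotropic pixels).
    image_id : str
        Opaque identifier used in error messages and reports.
    """

    width: int
    height: int
    spacing_row: float
    spacing_col: Optional[float] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"image {self.image_id!r}: non-positive size "
                f"{self.width}x{self.height}"
            )
        if self.spacing_col is None:
            object.__setattr__(self, "spacing_col", self.spacing_row)
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise SpacingError(
                f"image {self.image_id!r}: pixel spacing must be positive, "
                f"got row={self.spacing_row} col={self.spacing_col}"
            )


@dataclass(frozen=True)
class Point:
    """A pixel location: ``x`` is the column, ``y`` the row (0-based)."""

    x: float
    y: float

    def bound_check(self, meta: ImageMeta) -> None:
        if not (0 <= self.x < meta.width and 0 <= self.y < meta.height):
            raise ValueError(
                f"point ({self.x}, {self.y}) outside image "
                f"{meta.image_id!r} of size {meta.width}x{meta.height}"
            )


# Landmark names accepted by the serialization layer.
LANDMARK_NAMES = (
    "carina",
    "cavoatrial_junction",
    "ge_junction",
)


@dataclass
class LandmarkSet:
    """Named anatomical reference points for one radiograph.

    The carina anchors the endotracheal-tube rule, the cavoatrial junction
    the central-venous-catheter rule and the gastro-esophageal junction the
    nasogastric-tube rule.  ``t1_level_y`` and ``aortic_arch_upper_y`` are
    optional row coordinates enabling the "at T1 or above" clause.  Any
    landmark may be absent; rules that need an absent landmark are skipped,
    never guessed.
    """

    carina: Optional[Point] = None
    cavoatrial_junction: Optional[Point] = None
    ge_junction: Optional[Point] = None
    t1_level_y: Optional[float] = None
    aortic_arch_upper_y: Optional[float] = None

    def present(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


def _require_spacing(meta: ImageMeta) -> None:
    if meta.spacing_row is None or meta.spacing_col is None:
        raise SpacingError(f"image {meta.image_id!r}: pixel spacing missing")


def vertical_separation_mm(tip: Point, landmark: Point, meta: ImageMeta) -> float:
    """Signed cranio-caudal offset of ``tip`` relative to ``landmark`` in mm.

    Positive when the tip is *above* (cranial to) the landmark, which in the
    image convention means the tip has the smaller row coordinate:

        ``(landmark.y - tip.y) * spacing_row``
    """
    _require_spacing(meta)
    return (landmark.y - tip.y) * meta.spacing_row


def euclidean_distance_mm(a: Point, b: Point, meta: ImageMeta) -> float:
    """Straight-line distance between two points in mm, anisotropy-aware."""
    _require_spacing(meta)
    dx = (a.x - b.x) * meta.spacing_col
    dy = (a.y - b.y) * meta.spacing_row
    return math.hypot(dx, dy)
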