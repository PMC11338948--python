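"""Tip extraction and line measurement from per-class binary mask channels.

The upstream segmentation network emits one binary channel per class —
"NGT line", "CVC line", "CVC tip" and "ETT tip".  This module turns those
raster channels into geometry: connected components, tip coordinates, the
visible arc length of a line, and the incompletely-imaged flag.  The NGT has
no tip channel, so its tip is recovered from the line skeleton (see
:func:`ngt_tip_from_line`).

All masks are 2-D arrays with values in {0, 1} (booleans accepted), indexed
``[row, col]`` consistently with :mod:`cxrtubes.geometry`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .geometry import ImageMeta, Point, euclidean_distance_mm

logger = logging.getLogger(__name__)


@dataclass
class MaskChannelSet:
    """The four per-class mask channels of one radiograph."""

    ngt_line: np.ndarray
    cvc_line: np.ndarray
    cvc_tip: np.ndarray
    ett_tip: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        shape = (self.meta.height, self.meta.width)
        for name in ("ngt_line", "cvc_line", "cvc_tip", "ett_tip"):
            ch = getattr(self, name)
            if ch.shape != shape:
                raise ValueError(
                    f"channel {name} has shape {ch.shape}, expected {shape}"
                )


@dataclass(frozen=True)
class Component:
    """One 8-connected foreground component.

    ``centroid`` is rounded to the nearest pixel for reporting;
    ``centroid_exact`` keeps the fractional value.  ``bbox`` is
    (min_x, min_y, max_x, max_y) inclusive.
    """

    pixel_count: int
    centroid: Point
    centroid_exact: tuple
    bbox: tuple
    touches_border: bool


@dataclass(frozen=True)
class TipDetection:
    tube_kind: str
    tip: Point
    source_component: Component
    selection_rule: str  # "largest" | "nearest_to_landmark"


def _validate_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask is not binary; values found: {vals[:10]}")
    return mask.astype(bool)


def find_components(mask: np.ndarray) -> List[Component]:
    """8-connected components of a binary mask.

    Sorted by pixel count descending; ties broken by bounding-box
    (min_y, min_x) ascending so the ordering is deterministic.
    """
    mask = _validate_binary(mask)
    labeled = cc_label(mask, connectivity=2)
    h, w = mask.shape
    comps: List[Component] = []
    for rp in regionprops(labeled):
        min_row, min_col, max_row, max_col = rp.bbox  # max exclusive
        cy, cx = rp.centroid
        comps.append(
            Component(
                pixel_count=int(rp.area),
                centroid=Point(x=int(round(cx)), y=int(round(cy))),
                centroid_exact=(cx, cy),
                bbox=(min_col, min_row, max_col - 1, max_row - 1),
                touches_border=(
                    min_row == 0
                    or min_col == 0
                    or max_row == h
                    or max_col == w
                ),
            )
        )
    comps.sort(key=lambda c: (-c.pixel_count, c.bbox[1], c.bbox[0]))
    return comps


def select_tip(
    components: Sequence[Component],
    tube_kind: str,
    meta: ImageMeta,
    reference: Optional[Point] = None,
) -> Optional[TipDetection]:
    """Pick the tip component for a tube.

    With a reference landmark (e.g. the cavoatrial junction for CVCs) the
    component whose centroid lies closest to it wins, so that when several
    catheters are present the one nearest the reference anatomy is assessed.
    Without a reference the largest component wins.  ``None`` means "tube
    not detected" and is a valid outcome, not an error.
    """
    if not components:
        return None
    if reference is not None:
        best = min(
            enumerate(components),
            key=lambda ic: (
                euclidean_distance_mm(
                    Point(*ic[1].centroid_exact), reference, meta
                ),
                -ic[1].pixel_count,
                ic[0],
            ),
        )[1]
        rule = "nearest_to_landmark"
    else:
        best = components[0]  # list is sorted largest-first
        rule = "largest"
    return TipDetection(
        tube_kind=tube_kind, tip=best.centroid, source_component=best,
        selection_rule=rule,
    )


# -- skeleton machinery -------------------------------------------------

# pixel offsets defining each undirected 8-neighbour edge exactly once
_EDGE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class LineSkeleton:
    """Skeleton of the largest component of a line mask, as a weighted graph.

    Nodes are skeleton pixels; edges join 8-adjacent pixels with weight equal
    to the physical step length (axial steps weigh one pixel pitch, diagonal
    steps ``sqrt(spacing_row^2 + spacing_col^2)``).  Arc lengths along the
    catheter are geodesic distances in this graph.
    """

    def __init__(self, line_mask: np.ndarray, meta: ImageMeta):
        self.meta = meta
        mask = _validate_binary(line_mask)
        labeled = cc_label(mask, connectivity=2)
        if labeled.max() == 0:
            self._coords = np.empty((0, 2), dtype=int)
            self._graph = None
            return
        counts = np.bincount(labeled.ravel())
        counts[0] = 0
        biggest = int(counts.argmax())
        sub = labeled == biggest
        # skeletonize only the bounding box of the component for speed
        rows, cols = np.nonzero(sub)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        skel = skeletonize(sub[r0:r1, c0:c1])
        rr, cc = np.nonzero(skel)
        coords = np.column_stack([rr + r0, cc + c0])
        self._coords = coords
        self._graph = self._build_graph(skel, r0, c0)

    def _build_graph(self, skel: np.ndarray, r0: int, c0: int):
        n = self._coords.shape[0]
        idx = -np.ones(skel.shape, dtype=np.int64)
        rr, cc = self._coords[:, 0] - r0, self._coords[:, 1] - c0
        idx[rr, cc] = np.arange(n)
        sr, sc = self.meta.spacing_row, self.meta.spacing_col
        diag = math.hypot(sr, sc)
        weight = {(0, 1): sc, (1, 0): sr, (1, 1): diag, (1, -1): diag}
        srcs, dsts, wts = [], [], []
        padded = np.pad(idx, 1, constant_values=-1)
        for dy, dx in _EDGE_OFFSETS:
            nb = padded[1 + dy: 1 + dy + skel.shape[0],
                        1 + dx: 1 + dx + skel.shape[1]]
            here = idx[rr, cc]
            there = nb[rr, cc]
            ok = there >= 0
            srcs.append(here[ok])
            dsts.append(there[ok])
            wts.append(np.full(int(ok.sum()), weight[(dy, dx)]))
        if not srcs or all(len(s) == 0 for s in srcs):
            return coo_matrix((n, n))
        s = np.concatenate(srcs)
        d = np.concatenate(dsts)
        w = np.concatenate(wts)
        return coo_matrix((w, (s, d)), shape=(n, n))

    @property
    def empty(self) -> bool:
        return self._coords.shape[0] == 0

    @property
    def n_nodes(self) -> int:
        return self._coords.shape[0]

    def point(self, node: int) -> Point:
        r, c = self._coords[node]
        return Point(x=int(c), y=int(r))

    def nearest_node(self, p: Point) -> int:
        dy = (self._coords[:, 0] - p.y) * self.meta.spacing_row
        dx = (self._coords[:, 1] - p.x) * self.meta.spacing_col
        return int(np.argmin(dx * dx + dy * dy))

    def degrees(self) -> np.ndarray:
        if self._graph is None:
            return np.zeros(0, dtype=int)
        g = self._graph.tocsr()
        und = g + g.T
        return np.diff(und.indptr)

    def endpoints(self) -> np.ndarray:
        """Nodes with exactly one neighbour (free ends of the curve)."""
        return np.nonzero(self.degrees() == 1)[0]

    def arc_distances_from(self, node: int) -> np.ndarray:
        g = self._graph.tocsr()
        return dijkstra(g + g.T, directed=False, indices=node)

    def diameter_path(self) -> np.ndarray:
        """Longest geodesic between two skeleton endpoints, as node indices.

        Two sweeps of Dijkstra (the classic tree-diameter trick); spur
        branches off the main curve are excluded.  Falls back to all nodes
        in raster order for degenerate skeletons without two endpoints.
        """
        ends = self.endpoints()
        if ends.size < 2:
            return np.arange(self.n_nodes)
        g = (self._graph + self._graph.T).tocsr()
        d0 = dijkstra(g, directed=False, indices=int(ends[0]))
        d0e = np.where(np.isfinite(d0[ends]), d0[ends], -1.0)
        a = int(ends[int(np.argmax(d0e))])
        d, pred = dijkstra(g, directed=False, indices=a,
                           return_predecessors=True)
        de = np.where(np.isfinite(d[ends]), d[ends], -1.0)
        b = int(ends[int(np.argmax(de))])
        path = [b]
        while path[-1] != a and pred[path[-1]] >= 0:
            path.append(int(pred[path[-1]]))
        return np.asarray(path[::-1])

    def polygonal_length_mm(self, step: int = 4) -> float:
        """Arc length of the diameter path by chord resampling.

        Summing raw pixel steps overestimates oblique digital curves by up
        to ~8% (the chain-code bias), so the path is resampled every
        ``step`` pixels and chord lengths are summed; for straight and
        gently curving catheters this is accurate to about a pixel.
        """
        if self.empty:
            return 0.0
        path = self.diameter_path()
        if path.size < 2:
            return 0.0
        nodes = np.concatenate([path[::step], path[-1:]])
        pts = self._coords[nodes].astype(float)
        d = np.diff(pts, axis=0)
        d[:, 0] *= self.meta.spacing_row
        d[:, 1] *= self.meta.spacing_col
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def visible_line_length_mm(line_mask: np.ndarray, meta: ImageMeta) -> float:
    """Arc length in mm of the largest line component's skeleton.

    Measured along the skeleton's longest endpoint-to-endpoint geodesic
    with chord resampling (see :meth:`LineSkeleton.polygonal_length_mm`),
    which avoids both spur double-counting and the chain-code bias of raw
    pixel-step summation.  Empty masks measure 0.
    """
    return LineSkeleton(line_mask, meta).polygonal_length_mm()


def is_incompletely_imaged(
    line_mask: np.ndarray, tip_components: Sequence[Component]
) -> bool:
    """True iff the line runs off the film and no in-field tip was found.

    "No tube present" (blank channels) is distinct from "incompletely
    imaged" and returns False.
    """
    comps = find_components(line_mask)
    if not comps:
        return False
    interior_tip = any(not c.touches_border for c in tip_components)
    return comps[0].touches_border and not interior_tip


def ngt_tip_from_line(
    line_mask: np.ndarray, meta: ImageMeta, carina: Optional[Point] = None
) -> Optional[Point]:
    """Locate the NGT tip from the line channel alone.

    The segmentation model emits no NGT tip channel, so the tip is defined
    as the skeleton endpoint farthest (by arc length) from the skeleton
    point nearest the carina — the tube enters at the pharynx, near the
    carina level, and its far end is the tip.  Endpoints on the image
    border are excluded when an interior endpoint exists: a border endpoint
    is where the tube enters (or leaves) the film, not a tip.  Without a
    carina the lowermost endpoint is used.  This is a gap-filling
    definition; every use is logged.
    """
    skel = LineSkeleton(line_mask, meta)
    if skel.empty:
        return None
    ends = skel.endpoints()
    if ends.size > 0:
        rc = skel._coords[ends]
        interior = (
            (rc[:, 0] > 0) & (rc[:, 0] < meta.height - 1)
            & (rc[:, 1] > 0) & (rc[:, 1] < meta.width - 1)
        )
        if interior.any():
            ends = ends[interior]
    if ends.size == 0:
        # degenerate (loop or single pixel): fall back to lowermost pixel
        node = int(np.argmax(skel._coords[:, 0]))
        logger.info("NGT tip fallback: no skeleton endpoints; lowermost pixel")
        return skel.point(node)
    if carina is not None:
        src = skel.nearest_node(carina)
        d = skel.arc_distances_from(src)
        d_ends = d[ends]
        d_ends[~np.isfinite(d_ends)] = -1.0
        tip_node = int(ends[np.argmax(d_ends)])
        logger.debug("NGT tip from line skeleton, carina-anchored")
    else:
        order = np.lexsort((skel._coords[ends, 1], skel._coords[ends, 0]))
        tip_node = int(ends[order[-1]])
        logger.info("NGT tip fallback: carina absent; lowermost endpoint used")
    return skel.point(tip_node)


def arc_length_beyond_mm(
    line_mask: np.ndarray, meta: ImageMeta, landmark: Point, tip: Point
) -> float:
    """Arc length along the line from the landmark's nearest skeleton point
    to the tip's nearest skeleton point.

    Used for "beyond the gastro-esophageal junction" distances, which follow
    the tube's curve rather than a straight line.
    """
    skel = LineSkeleton(line_mask, meta)
    if skel.empty:
        return 0.0
    src = skel.nearest_node(landmark)
    dst = skel.nearest_node(tip)
    d = skel.arc_distances_from(src)[dst]
    return float(d) if np.isfinite(d) else 0.0
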