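"""Convex-hull descriptors of rolled-upness.

A tightly rolled cross-section has a compact convex hull: its maximum
diameter D shrinks relative to the (unrolling-invariant) strip length L.
The logarithmic index ln(L / D) is 0 for a flat strip and grows with
rolling; the log form stabilises standard errors across treatments.

The hull is computed on the raw digitised points — smoothing does not
affect it — while the length in the ratio comes from the spline fit. The
midrib landmark, when present, is excluded from the hull input (it marks
the protruding central rib, not the lamina outline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import DegenerateHull, NonPositiveInput

__all__ = [
    "HullResult",
    "convex_hull",
    "max_diameter",
    "log_index",
    "hull_measures",
]


@dataclass
class HullResult:
    """Convex hull of a cross-section and its derived rolling index."""

    hull_vertices: np.ndarray  # (k, 2), counter-clockwise
    max_diameter: float  # mm
    log_index: Optional[float] = None  # ln(length / max_diameter)


def convex_hull(
    points: Sequence,
    exclude_midrib: bool = True,
    midrib_index: Optional[int] = None,
) -> np.ndarray:
    """Counter-clockwise convex hull vertices of a planar point set.

    Collinear boundary points are dropped. Raises DegenerateHull when fewer
    than 3 points remain after midrib exclusion or when all points are
    collinear (a flat strip); callers should then fall back to the maximum
    pairwise distance as the diameter.
    """
    pts = np.asarray(points, dtype=float)
    if exclude_midrib and midrib_index is not None:
        pts = np.delete(pts, midrib_index, axis=0)
    if len(pts) < 3:
        raise DegenerateHull(f"need at least 3 points, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHull("points are collinear (flat strip)") from exc
    return pts[hull.vertices]  # scipy returns CCW order in 2-D


def max_diameter(hull_vertices: Sequence) -> float:
    """Largest pairwise distance between hull vertices (the set diameter).

    For a convex polygon the diameter over vertices equals the diameter of
    the full point set; vertex counts are small, so the all-pairs scan is
    exact and cheap.
    """
    verts = np.asarray(hull_vertices, dtype=float)
    if len(verts) < 2:
        raise DegenerateHull("diameter needs at least 2 vertices")
    return float(pdist(verts).max())


def rotating_calipers_diameter(hull_vertices: Sequence) -> float:
    """Hull diameter by rotating calipers over antipodal vertex pairs.

    Independent of :func:`max_diameter`; the two must agree on any convex
    polygon (used as a cross-check).
    """
    verts = np.asarray(hull_vertices, dtype=float)
    k = len(verts)
    if k < 2:
        raise DegenerateHull("diameter needs at least 2 vertices")
    if k == 2:
        return float(np.linalg.norm(verts[1] - verts[0]))
    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    best = 0.0
    j = 1
    for i in range(k):
        edge = verts[(i + 1) % k] - verts[i]
        # advance the antipodal pointer while the supporting distance grows
        while True:
            nxt = (j + 1) % k
            cur = cross2(edge, verts[j] - verts[i])
            adv = cross2(edge, verts[nxt] - verts[i])
            if adv > cur:
                j = nxt
            else:
                break
        for v in (verts[i], verts[(i + 1) % k]):
            best = max(best, float(np.linalg.norm(verts[j] - v)))
    return best


def log_index(length: float, diameter: float) -> float:
    """Natural logarithm of strip length over hull maximum diameter.

    Zero for a perfectly flat strip (length equals diameter), increasing
    as the section rolls up and the hull tightens.
    """
    if not (length > 0 and diameter > 0):
        raise NonPositiveInput(
            f"length and diameter must be positive, got {length}, {diameter}"
        )
    return math.log(length / diameter)


def hull_measures(
    points: Sequence,
    length: Optional[float] = None,
    exclude_midrib: bool = True,
    midrib_index: Optional[int] = None,
) -> HullResult:
    """Hull, diameter and (if a length is given) the logarithmic index.

    Degenerate (collinear) sections fall back to the maximum pairwise
    distance over the raw points as the diameter.
    """
    pts = np.asarray(points, dtype=float)
    try:
        verts = convex_hull(pts, exclude_midrib=exclude_midrib,
                            midrib_index=midrib_index)
        diam = max_diameter(verts)
    except DegenerateHull:
        if exclude_midrib and midrib_index is not None:
            pts = np.delete(pts, midrib_index, axis=0)
        verts = pts
        diam = float(pdist(pts).max())
        if diam <= 0:
            raise
    idx = log_index(length, diam) if length is not None else None
    return HullResult(hull_vertices=verts, max_diameter=diam, log_index=idx)
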