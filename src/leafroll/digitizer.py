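"""Image-to-coordinates digitisation of leaf cross-sections.

Mirrors the manual processing sequence used at the microscope: the
overexposed micro-photograph is binarised to isolate the bright strip,
thinned to a one-pixel skeleton equidistant from the strip boundaries, and
the skeleton's dominant path is resampled into an ordered chain of roughly
equally spaced points in millimetres. Side branches of the skeleton
(imaging spurs) are pruned by keeping the longest endpoint-to-endpoint
geodesic.

Output coordinates are y-up: image rows are flipped so that the adaxial
surface sits at larger y (controlled by ``SectionImage.adaxial_up``), and
the chain is ordered left-to-right (x increasing from first to last point).
Under that convention, positive signed curvature downstream means the
centre of curvature lies on the adaxial side.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize as _thin

from .errors import (
    ChainTooShort,
    CyclicSkeleton,
    DegenerateSkeleton,
    NoForeground,
)
from .types import BinaryMask, DigitizedCrossSection, SectionImage, SkeletonChain

__all__ = [
    "load_image",
    "binarize",
    "skeletonize",
    "digitize",
    "digitize_image",
]


def load_image(
    path, mm_per_px: float, adaxial_up: bool = True
) -> SectionImage:
    """Read a PNG/TIFF micro-photograph as an 8-bit grayscale SectionImage.

    RGB inputs are converted by luminance.
    """
    with Image.open(path) as im:
        gray = im.convert("L")
        pixels = np.asarray(gray, dtype=np.uint8)
    return SectionImage(pixels=pixels, mm_per_px=mm_per_px, adaxial_up=adaxial_up)


def binarize(
    image: SectionImage,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_area_frac: float = 0.01,
) -> BinaryMask:
    """Threshold the image and keep the largest connected bright component.

    Components smaller than ``min_area_frac`` of the largest component are
    speck noise (dust in the PEG solution) and are discarded; since exactly
    one strip is expected per image, only the largest component survives.
    """
    pixels = image.pixels
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed thresholding requires fixed_threshold")
        thr = fixed_threshold
    elif method == "otsu":
        if pixels.min() == pixels.max():
            raise NoForeground("uniform image: no foreground to threshold")
        thr = threshold_otsu(pixels)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    fg = pixels > thr
    if not fg.any():
        raise NoForeground("empty mask after thresholding")
    labels, n_comp = label(fg, connectivity=2, return_num=True)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if sizes[largest] == 0:
        raise NoForeground("empty mask after component cleanup")
    return BinaryMask(pixels=labels == largest)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph with Euclidean step weights."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (r + dr, c + dc)
            if nb in pix:
                g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def skeletonize(mask: BinaryMask, cycle_tol: int = 16) -> SkeletonChain:
    """Thin the mask to one pixel width and extract the dominant midline.

    The skeleton is treated as a graph; the returned chain is the longest
    geodesic between skeleton endpoints (degree-1 pixels), which prunes
    spurs off the main path. A skeleton whose cycles exceed ``cycle_tol``
    pixels (e.g. a strip rolled tightly enough to self-touch) cannot be
    reduced to a simple path and raises CyclicSkeleton.
    """
    if not mask.pixels.any():
        raise DegenerateSkeleton("empty mask")
    skel = _thin(mask.pixels)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        raise DegenerateSkeleton("skeleton vanished during thinning")

    for cycle in nx.cycle_basis(g):
        if len(cycle) > cycle_tol:
            raise CyclicSkeleton(
                f"skeleton cycle of {len(cycle)} pixels exceeds tolerance "
                f"{cycle_tol}"
            )

    endpoints = [n for n in g.nodes if g.degree(n) <= 1]
    if not endpoints:
        raise CyclicSkeleton("skeleton has no endpoints (closed loop)")

    # Longest geodesic between endpoints; endpoint counts are small, so an
    # all-endpoint-pairs Dijkstra is exact even off trees (small cycles).
    best_len, best_pair = -1.0, None
    for src in endpoints:
        dist, _ = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints:
            if dst in dist and dist[dst] > best_len:
                best_len, best_pair = dist[dst], (src, dst)
    path = nx.dijkstra_path(g, *best_pair, weight="weight")
    if len(path) < 5:
        raise DegenerateSkeleton(
            f"longest skeleton path has only {len(path)} pixels"
        )
    return SkeletonChain(pixels=np.asarray(path, dtype=int))


def _smooth_chain(px: np.ndarray, window: int) -> np.ndarray:
    """Moving-average sub-pixel refinement of the chain path.

    Thinning leaves +/- half-pixel jitter on the centreline; averaging
    positions over a short window removes it with negligible geometric
    distortion for curvature radii much larger than the window. Endpoints
    are kept fixed.
    """
    if window < 2 or len(px) < window:
        return px
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(px, ((pad, pad), (0, 0)), mode="edge")
    out = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in (0, 1)]
    )[: len(px)]
    out[0], out[-1] = px[0], px[-1]
    return out


def digitize(
    chain: SkeletonChain,
    image: SectionImage,
    n_points: int = 35,
    midrib: Optional[tuple[int, int]] = None,
    smooth_window: int = 5,
) -> DigitizedCrossSection:
    """Resample the skeleton chain into n_points scaled (x, y) coordinates.

    Points are placed at equal path spacing along the pixel chain (matching
    the roughly-equal-spacing rule of manual digitisation; 35 = 17 points
    per half-strip plus the shared midrib point). The pixel path first gets
    a ``smooth_window``-pixel moving-average refinement to sub-pixel
    accuracy. Pixel positions are converted to mm, the row axis is flipped
    so y points up, and the chain is ordered with x increasing. A midrib
    pixel, if supplied, is snapped to the nearest sampled point.
    """
    if len(chain) < n_points:
        raise ChainTooShort(
            f"chain of {len(chain)} pixels cannot yield {n_points} points"
        )
    px = _smooth_chain(chain.pixels.astype(float), smooth_window)
    steps = np.linalg.norm(np.diff(px, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    targets = np.linspace(0.0, cum[-1], n_points)
    rows = np.interp(targets, cum, px[:, 0])
    cols = np.interp(targets, cum, px[:, 1])

    s = image.mm_per_px
    h = image.pixels.shape[0]
    x = cols * s
    y = (h - 1 - rows) * s if image.adaxial_up else rows * s

    pts = np.column_stack([x, y])
    # Left-to-right ordering makes the curvature formula's sign match the
    # adaxial convention. C-shaped sections can have end-to-end x spans near
    # zero, where "left to right" is ill-defined; there the chain starts at
    # the lower endpoint instead, which keeps an adaxially curling (involute)
    # section positive.
    dx = pts[-1, 0] - pts[0, 0]
    tol = 0.05 * max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
    if dx < -tol or (abs(dx) <= tol and pts[-1, 1] < pts[0, 1]):
        pts = pts[::-1].copy()

    midrib_index = None
    if midrib is not None:
        mr, mc = midrib
        mx = mc * s
        my = (h - 1 - mr) * s if image.adaxial_up else mr * s
        midrib_index = int(
            np.argmin(np.linalg.norm(pts - np.array([mx, my]), axis=1))
        )

    return DigitizedCrossSection(
        points=pts,
        midrib_index=midrib_index,
        mm_per_px=s,
        adaxial_up=image.adaxial_up,
    )


def digitize_image(
    image: SectionImage,
    n_points: int = 35,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    midrib: Optional[tuple[int, int]] = None,
) -> DigitizedCrossSection:
    """Full image-to-coordinates pipeline: binarise, skeletonise, digitise."""
    mask = binarize(image, method=method, fixed_threshold=fixed_threshold)
    chain = skeletonize(mask)
    return digitize(chain, image, n_points=n_points, midrib=midrib)
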