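"""Synthetic strips and simulated genotype-by-osmoticum experiments.

Ground-truth geometry for validating the measurement pipeline, plus a
phenomenological generator of whole experiments contrasting "high-roller"
and "low-roller" genotype groups across osmotic-potential treatments.

Shapes are built by unit-speed construction from a prescribed curvature
profile kappa(u), u in [0, 1] along the strip:

    theta(s) = integral of kappa,  x(s) = integral of cos(theta),
    y(s) = integral of sin(theta),

evaluated by fine-step quadrature, then resampled at equal arc length. The
generator therefore knows the exact curvature, length, chord and hull of
every strip it emits — these analytic values are the oracles the
measurement modules are tested against.

The experiment generator models each strip as an arc whose mean curvature
follows the genotype's response to osmotic potential (anchored to the
reported group contrasts: low rollers from -0.137 to +0.022 mm^-1 and high
rollers from +0.120 to +0.452 mm^-1 between -0.06 and -2.82 MPa), with
left/right asymmetry, between-strip curvature spread, osmotic shrinkage of
strip length, and additive digitisation noise on the coordinates. All
randomness flows from one integer seed through spawned child streams, so
sub-streams are independent and runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .errors import InvalidSpec
from .io import MANIFEST_COLUMNS, write_coords_csv
from .types import DigitizedCrossSection, SectionImage

__all__ = [
    "ShapeSpec",
    "GenotypeModel",
    "LOW_ROLLER",
    "HIGH_ROLLER",
    "DEFAULT_NOISE_SD",
    "DEFAULT_STRIP_LENGTH_MM",
    "make_shape",
    "simulate_experiment",
    "rasterize",
]

#: Isotropic digitisation noise on point coordinates, mm (about the
#: positional uncertainty of clicking a skeleton point at the microscope).
DEFAULT_NOISE_SD = 0.02

#: Width of a flattened flag-leaf strip cross-section at full turgor, mm.
DEFAULT_STRIP_LENGTH_MM = 15.0


@dataclass
class ShapeSpec:
    """Recipe for one synthetic strip of known geometry.

    kind "line" ignores kappa; "arc" uses a constant kappa (mm^-1); and
    "curvature_function" takes kappa as a callable of relative position
    u in [0, 1]. noise_sd is the SD of isotropic Gaussian noise added to
    both coordinates of every sampled point.
    """

    kind: str  # line | arc | curvature_function
    length: float  # mm
    kappa: Union[float, Callable[[np.ndarray], np.ndarray], None] = None
    n_points: int = 35
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("line", "arc", "curvature_function"):
            raise InvalidSpec(f"unknown shape kind {self.kind!r}")
        if not self.length > 0:
            raise InvalidSpec("length must be positive")
        if self.n_points < 5:
            raise InvalidSpec("n_points must be at least 5")
        if self.noise_sd < 0:
            raise InvalidSpec("noise_sd must be non-negative")
        if self.kind == "arc" and not np.isscalar(self.kappa):
            raise InvalidSpec("arc requires a scalar kappa")
        if self.kind == "curvature_function" and not callable(self.kappa):
            raise InvalidSpec("curvature_function requires a callable kappa")


def make_shape(spec: ShapeSpec) -> DigitizedCrossSection:
    """Sample a strip of prescribed curvature at equal arc-length spacing."""
    L = spec.length
    n = spec.n_points
    s_samples = np.linspace(0.0, L, n)

    if spec.kind == "line" or (spec.kind == "arc" and spec.kappa == 0):
        x = s_samples
        y = np.zeros(n)
    elif spec.kind == "arc":
        k = float(spec.kappa)
        # circle of radius 1/|k|, starting at the origin heading +x;
        # positive kappa curls toward +y (the adaxial side)
        x = np.sin(k * s_samples) / k
        y = (1.0 - np.cos(k * s_samples)) / k
    else:
        m = 10_000  # quadrature step length/1e4
        s_fine = np.linspace(0.0, L, m + 1)
        kappa_fine = np.asarray(spec.kappa(s_fine / L), dtype=float)
        theta = cumulative_trapezoid(kappa_fine, s_fine, initial=0.0)
        x_fine = cumulative_trapezoid(np.cos(theta), s_fine, initial=0.0)
        y_fine = cumulative_trapezoid(np.sin(theta), s_fine, initial=0.0)
        x = np.interp(s_samples, s_fine, x_fine)
        y = np.interp(s_samples, s_fine, y_fine)

    pts = np.column_stack([x, y])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    return DigitizedCrossSection(points=pts)


@dataclass
class GenotypeModel:
    """Phenomenological rolling response of one genotype.

    kappa_anchors maps osmotic potential (MPa, negative) to the mean true
    curvature (mm^-1) of the strip at equilibrium; values are linearly
    interpolated between anchors and must be non-decreasing as the
    potential drops (rolling only tightens with dehydration). asymmetry
    scales one half-strip's curvature up and the other down by the same
    factor (one leaf side rolls more than the other); shrink_per_mpa is
    the fractional strip-length loss per MPa of dehydration; strip_sd is
    the between-strip SD of mean curvature within a treatment cell.
    """

    name: str
    group: str  # low_roller | high_roller
    kappa_anchors: dict[float, float]
    asymmetry: float = 0.1
    shrink_per_mpa: float = 0.01
    strip_sd: float = 0.05  # mm^-1

    def __post_init__(self) -> None:
        if not 0 <= self.asymmetry < 1:
            raise InvalidSpec("asymmetry must be in [0, 1)")
        psis = sorted(self.kappa_anchors)  # ascending: most stressed first
        kappas = [self.kappa_anchors[p] for p in psis]
        if any(b > a + 1e-12 for a, b in zip(kappas, kappas[1:])):
            raise InvalidSpec(
                "kappa_anchors must be non-decreasing with decreasing potential"
            )
        self._psis = np.asarray(psis, dtype=float)
        self._kappas = np.asarray(kappas, dtype=float)

    def kappa_at(self, psi: float) -> float:
        """Mean true curvature (mm^-1) at osmotic potential psi (MPa)."""
        return float(np.interp(psi, self._psis, self._kappas))


LOW_ROLLER = GenotypeModel(
    name="low_roller_1",
    group="low_roller",
    kappa_anchors={-0.06: -0.137, -1.38: -0.078, -2.82: 0.022},
    shrink_per_mpa=0.01,
)

HIGH_ROLLER = GenotypeModel(
    name="high_roller_1",
    group="high_roller",
    kappa_anchors={-0.06: 0.120, -1.38: 0.159, -2.82: 0.452},
    shrink_per_mpa=0.03,
)


def _strip_section(
    model: GenotypeModel,
    psi: float,
    rng: np.random.Generator,
    n_points: int,
    noise_sd: float,
    base_length: float,
) -> DigitizedCrossSection:
    kappa_bar = model.kappa_at(psi) + rng.normal(0.0, model.strip_sd)
    side = rng.choice([-1.0, 1.0])
    k_left = kappa_bar * (1.0 + side * model.asymmetry)
    k_right = kappa_bar * (1.0 - side * model.asymmetry)
    length = base_length * (1.0 - model.shrink_per_mpa * abs(psi))

    def kappa_fn(u: np.ndarray) -> np.ndarray:
        return np.where(u < 0.5, k_left, k_right)

    spec = ShapeSpec(
        kind="curvature_function",
        length=length,
        kappa=kappa_fn,
        n_points=n_points,
        noise_sd=0.0,
    )
    section = make_shape(spec)
    if noise_sd > 0:
        section.points = section.points + rng.normal(
            0.0, noise_sd, size=section.points.shape
        )
    # midrib landmark at the half-strip boundary
    section.midrib_index = n_points // 2
    return section


def simulate_experiment(
    genotypes: Sequence[GenotypeModel],
    psi_levels: Sequence[float],
    reps: int,
    seed: int,
    n_points: int = 35,
    noise_sd: float = DEFAULT_NOISE_SD,
    base_length_mm: float = DEFAULT_STRIP_LENGTH_MM,
    outdir: Optional[Union[str, Path]] = None,
) -> tuple[pd.DataFrame, dict[str, DigitizedCrossSection]]:
    """Simulate one strip per genotype x potential x replicate.

    Returns a manifest table plus the sections keyed by file name (the same
    dialect the measurement pipeline consumes); when ``outdir`` is given,
    writes manifest.csv and coords/*.csv there. Deterministic given seed.
    """
    if reps < 1:
        raise InvalidSpec("reps must be at least 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(genotypes) * len(psi_levels) * reps)

    rows = []
    sections: dict[str, DigitizedCrossSection] = {}
    i = 0
    for geno in genotypes:
        for psi in psi_levels:
            for rep in range(1, reps + 1):
                rng = np.random.default_rng(children[i])
                i += 1
                sec = _strip_section(
                    geno, psi, rng, n_points, noise_sd, base_length_mm
                )
                fname = f"coords/{geno.name}_psi{psi:+.2f}_rep{rep:03d}.csv"
                sec.meta = {
                    "genotype": geno.name,
                    "rolling_group": geno.group,
                    "psi_mpa": psi,
                    "replicate": rep,
                }
                sections[fname] = sec
                rows.append(
                    {
                        "file": fname,
                        "genotype": geno.name,
                        "rolling_group": geno.group,
                        "psi_mpa": psi,
                        "peg_conc_g_per_g": np.nan,
                        "replicate": rep,
                        "scale_mm_per_px": np.nan,
                    }
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "coords").mkdir(parents=True, exist_ok=True)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        for fname, sec in sections.items():
            write_coords_csv(sec, outdir / fname)
    return manifest, sections


def rasterize(
    section: DigitizedCrossSection,
    thickness_px: int = 5,
    mm_per_px: float = 0.05,
    pad_px: int = 10,
) -> SectionImage:
    """Render a section as a bright stroke on a dark 8-bit image.

    The polyline through the points is drawn one pixel wide and dilated to
    the requested stroke thickness (round caps). y is flipped back to image
    convention (row 0 at the top, adaxial up). The exact stroke mask is
    retained on the returned image for oracle comparisons.
    """
    if thickness_px < 3:
        raise InvalidSpec("thickness_px must be at least 3")
    radius = thickness_px // 2
    pts = section.points
    x, y = pts[:, 0], pts[:, 1]
    margin = pad_px + radius
    s = mm_per_px

    cols = (x - x.min()) / s + margin
    rows = (y.max() - y) / s + margin  # flip y-up back to rows-down
    h = int(np.ceil(rows.max())) + margin + 1
    w = int(np.ceil(cols.max())) + margin + 1
    h, w = max(h, 8), max(w, 8)

    centreline = np.zeros((h, w), dtype=bool)
    ri = np.round(rows).astype(int)
    ci = np.round(cols).astype(int)
    for k in range(len(pts) - 1):
        rr, cc = _draw_line(ri[k], ci[k], ri[k + 1], ci[k + 1])
        centreline[rr, cc] = True

    stroke = dilation(centreline, disk(radius))
    pixels = np.where(stroke, 255, 0).astype(np.uint8)
    return SectionImage(
        pixels=pixels,
        mm_per_px=mm_per_px,
        adaxial_up=True,
        stroke_mask=stroke,
    )
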