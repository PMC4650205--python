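"""Plain-text I/O: coordinate CSVs, manifests and results tables.

Coordinate CSV dialect (one file per strip)::

    # mm_per_px=<value>
    # adaxial_up=<true|false>
    index,x_mm,y_mm,is_midrib
    0,0.0000,1.2000,0
    ...

with 0-based indices and at most one row flagged ``is_midrib=1``.

Manifest CSV columns: ``file, genotype, rolling_group, psi_mpa,
peg_conc_g_per_g, replicate, scale_mm_per_px`` — exactly one of
psi_mpa / peg_conc_g_per_g is required per row; the other is derived
through the PEG calibration.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import DigitizedCrossSection

MANIFEST_COLUMNS = [
    "file",
    "genotype",
    "rolling_group",
    "psi_mpa",
    "peg_conc_g_per_g",
    "replicate",
    "scale_mm_per_px",
]

RESULTS_COLUMNS = [
    "strip_id",
    "genotype",
    "rolling_group",
    "psi_mpa",
    "replicate",
    "mean_curvature_mm",
    "scaled_mean_curvature",
    "strip_length_mm",
    "hull_diameter_mm",
    "log_index",
    "trace_used",
    "dt_used",
    "n_points",
]


def write_coords_csv(section: DigitizedCrossSection, path: str | Path) -> None:
    path = Path(path)
    mmpp = section.mm_per_px if section.mm_per_px is not None else math.nan
    lines = [
        f"# mm_per_px={mmpp}",
        f"# adaxial_up={str(section.adaxial_up).lower()}",
        "index,x_mm,y_mm,is_midrib",
    ]
    for i, (x, y) in enumerate(section.points):
        flag = 1 if section.midrib_index == i else 0
        lines.append(f"{i},{float(x)!r},{float(y)!r},{flag}")
    path.write_text("\n".join(lines) + "\n")


def read_coords_csv(path: str | Path) -> DigitizedCrossSection:
    path = Path(path)
    mm_per_px: Optional[float] = None
    adaxial_up = True
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "mm_per_px":
                v = float(val)
                mm_per_px = None if math.isnan(v) else v
            elif key == "adaxial_up":
                adaxial_up = val.strip().lower() in ("true", "1", "yes")
    df = pd.read_csv(path, skiprows=header_rows)
    pts = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    midrib_rows = np.nonzero(df["is_midrib"].to_numpy() == 1)[0]
    if len(midrib_rows) > 1:
        raise ValueError(f"{path}: more than one midrib flag")
    midrib_index = int(midrib_rows[0]) if len(midrib_rows) else None
    return DigitizedCrossSection(
        points=pts,
        midrib_index=midrib_index,
        mm_per_px=mm_per_px,
        adaxial_up=adaxial_up,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("file",) if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write the per-strip results table (full float precision round-trips)."""
    records.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
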