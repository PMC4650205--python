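"""Batch measurement, group summaries and fixed-effects ANOVA.

Orchestrates digitizer -> spline_curvature -> hull_index over a manifest of
strips, producing one record per strip, then aggregates records into the
group-by-potential table of means and standard errors and tests the
rolling-group and osmoticum effects with a fixed-effects two-way ANOVA
(group, potential, and their interaction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import io as lio
from .digitizer import digitize_image, load_image
from .errors import EmptyManifest, LeafrollError, SingularDesign
from .hull_index import hull_measures
from .peg_calibration import DEFAULT_CALIBRATION, PEGCalibration, psi_from_conc
from .spline_curvature import curvature_profile, fit_smoothing_spline, strip_measures
from .types import DigitizedCrossSection

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureConfig",
    "measure_strip",
    "measure_batch",
    "group_summary",
    "anova_two_way",
]


@dataclass
class MeasureConfig:
    """Measurement settings applied to every strip in a batch."""

    trace: float = 10.0
    dt: float = 0.25
    n_points: int = 35
    arc_length_weighted: bool = False
    boundary_trim_frac: float = 0.1
    exclude_midrib: bool = True


def measure_strip(
    section: DigitizedCrossSection, config: Optional[MeasureConfig] = None
) -> dict:
    """All rolled-upness measures for one digitised cross-section."""
    cfg = config or MeasureConfig()
    curve = fit_smoothing_spline(section, trace_target=cfg.trace)
    profile = curvature_profile(curve, dt=cfg.dt)
    meas = strip_measures(
        profile,
        arc_length_weighted=cfg.arc_length_weighted,
        boundary_trim_frac=cfg.boundary_trim_frac,
    )
    hull = hull_measures(
        section.points,
        length=meas.length,
        exclude_midrib=cfg.exclude_midrib,
        midrib_index=section.midrib_index,
    )
    return {
        "mean_curvature_mm": meas.mean_curvature,
        "scaled_mean_curvature": meas.scaled_mean_curvature,
        "strip_length_mm": meas.length,
        "hull_diameter_mm": hull.max_diameter,
        "log_index": hull.log_index,
        "max_curvature_mm": meas.max_curvature,
        "trace_used": curve.trace_achieved,
        "dt_used": cfg.dt,
        "n_points": section.n_points,
    }


def _resolve_section(
    fname: str,
    row: pd.Series,
    sections: Optional[Mapping[str, DigitizedCrossSection]],
    base_dir: Optional[Path],
    cfg: MeasureConfig,
) -> DigitizedCrossSection:
    if sections is not None and fname in sections:
        return sections[fname]
    if base_dir is None:
        raise FileNotFoundError(f"no source for strip {fname!r}")
    path = base_dir / fname
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".png", ".tif", ".tiff"):
        scale = float(row.get("scale_mm_per_px"))
        if not np.isfinite(scale):
            raise ValueError(f"{fname}: image input needs scale_mm_per_px")
        img = load_image(path, mm_per_px=scale)
        return digitize_image(img, n_points=cfg.n_points)
    return lio.read_coords_csv(path)


def measure_batch(
    manifest: Union[pd.DataFrame, str, Path],
    sections: Optional[Mapping[str, DigitizedCrossSection]] = None,
    base_dir: Optional[Union[str, Path]] = None,
    config: Optional[MeasureConfig] = None,
    calibration: PEGCalibration = DEFAULT_CALIBRATION,
) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every strip in a manifest.

    Inputs are taken from ``sections`` (in-memory, keyed by the manifest's
    file column) or loaded from ``base_dir`` (coordinate CSVs, or images
    digitised on the fly). Rows whose potential is missing but whose PEG
    concentration is given get psi derived through the calibration.
    Per-strip failures are logged and collected without aborting the batch.

    Returns
    -------
    (records, failures)
        records: one row per successfully measured strip;
        failures: list of {"file", "error"} dicts for the rest.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = lio.read_manifest(manifest)
    if len(manifest) == 0:
        raise EmptyManifest("manifest has no rows")
    base = Path(base_dir) if base_dir is not None else None
    cfg = config or MeasureConfig()

    records, failures = [], []
    for _, row in manifest.iterrows():
        fname = row["file"]
        try:
            psi = row.get("psi_mpa", np.nan)
            conc = row.get("peg_conc_g_per_g", np.nan)
            if not np.isfinite(psi):
                if np.isfinite(conc):
                    psi = psi_from_conc(calibration, float(conc))
                else:
                    psi = np.nan
            section = _resolve_section(fname, row, sections, base, cfg)
            rec = measure_strip(section, cfg)
            rec.update(
                strip_id=fname,
                genotype=row.get("genotype"),
                rolling_group=row.get("rolling_group"),
                psi_mpa=psi,
                replicate=row.get("replicate"),
            )
            records.append(rec)
        except (LeafrollError, FileNotFoundError, ValueError) as exc:
            logger.warning("strip %s failed: %s", fname, exc)
            failures.append({"file": fname, "error": str(exc)})

    cols = lio.RESULTS_COLUMNS + ["max_curvature_mm"]
    df = pd.DataFrame(records)
    if len(df):
        df = df[[c for c in cols if c in df.columns]]
    return df, failures


def group_summary(
    records: pd.DataFrame,
    values: tuple[str, ...] = ("mean_curvature_mm", "log_index"),
    by: tuple[str, ...] = ("rolling_group", "psi_mpa"),
) -> pd.DataFrame:
    """Cell means, standard errors and counts per group x potential.

    SE = sd / sqrt(n); cells with a single record report a missing (NaN)
    SE rather than zero, since the within-cell spread is undefined there.
    """
    if len(records) == 0:
        raise EmptyManifest("no records to summarise")
    grouped = records.groupby(list(by), sort=True)
    out = {}
    for v in values:
        agg = grouped[v].agg(["mean", "std", "count"])
        out[(v, "mean")] = agg["mean"]
        out[(v, "se")] = agg["std"] / np.sqrt(agg["count"])
        out[(v, "n")] = agg["count"]
    summary = pd.DataFrame(out)
    summary.columns = [f"{v}_{stat}" for v, stat in summary.columns]
    return summary.reset_index()


def anova_two_way(
    records: pd.DataFrame,
    response: str = "mean_curvature_mm",
    group_col: str = "rolling_group",
    psi_col: str = "psi_mpa",
    log_abs_transform: bool = False,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction on per-strip records.

    Factors are the rolling group and the osmotic-potential treatment
    (treated as categorical). For balanced designs the sums of squares
    equal the classical closed forms. ``log_abs_transform`` applies
    log(|response| + eps) first, a variance-stabilising option for designs
    where spread grows with dehydration.

    Returns a table with one row per effect (group, psi, interaction,
    residual) carrying df, sum_sq, mean_sq, F and p.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if response not in records.columns:
        raise ValueError(f"unknown response {response!r}")
    df = records[[response, group_col, psi_col]].dropna().copy()
    df.columns = ["y", "g", "p"]
    if df["g"].nunique() < 2 or df["p"].nunique() < 2:
        raise SingularDesign("need at least 2 levels per factor")
    if log_abs_transform:
        df["y"] = np.log(np.abs(df["y"]) + 1e-12)

    with np.errstate(divide="ignore", invalid="ignore"):
        model = ols("y ~ C(g) * C(p)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
    # a response without any variation leaves only floating-point noise in
    # the residual: F ratios are then meaningless, report them as missing
    if model.ssr <= 1e-12 * max(float(np.sum(df["y"] ** 2)), 1e-300):
        import warnings

        warnings.warn(
            "zero residual variance: F statistics undefined", stacklevel=2
        )
        table["F"] = np.nan
        table["PR(>F)"] = np.nan
    table = table.rename(
        index={
            "C(g)": "group",
            "C(p)": "psi",
            "C(g):C(p)": "group:psi",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table[["df", "sum_sq", "mean_sq", "F", "p"]]
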