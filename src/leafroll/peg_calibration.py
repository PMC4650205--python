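"""PEG 3350 osmoticum calibration.

Leaf strips are dehydrated by immersion in polyethylene-glycol (PEG 3350)
solutions; the water potential imposed on the tissue is set by the PEG
concentration. The concentration-to-potential map at 20 degrees C is a
second-order polynomial fitted to psychrometer measurements:

    Pi_PEG = a2 * c^2 + a1 * c + a0      [Pi in MPa, c in g PEG per g water]

with the default (psychrometer-derived) coefficients
a2 = -11.517, a1 = -1.0508, a0 = -0.0342 valid on c in [0, 0.55] g/g.
Concentrations above 0.45 g/g are viscous enough to mechanically impede
rolling, so evaluation there carries a warning.

The seven dehydration levels used in the reference experimental design are
kept as a named constant; they are measured values and differ slightly from
the polynomial's output at the matching concentrations, so neither is
silently substituted for the other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import NoRootInRange, OutOfRange, RankDeficient

__all__ = [
    "PEGCalibration",
    "DEFAULT_CALIBRATION",
    "TREATMENT_POTENTIALS_MPA",
    "psi_from_conc",
    "conc_from_psi",
    "fit_calibration",
]

#: Osmotic potentials (MPa) of the seven standard dehydration treatments.
TREATMENT_POTENTIALS_MPA = (-0.06, -0.43, -1.00, -1.38, -1.76, -2.38, -2.82)

#: Above this concentration solution viscosity can impede rolling.
VISCOSITY_WARNING_CONC = 0.45


@dataclass(frozen=True)
class PEGCalibration:
    """Quadratic map from PEG concentration (g/g) to osmotic potential (MPa)."""

    coeffs: tuple[float, float, float]  # (a2, a1, a0), highest degree first
    valid_range: tuple[float, float] = (0.0, 0.55)
    temperature_C: float = 20.0
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        a2, a1, a0 = self.coeffs
        if a0 > 0:
            raise ValueError("intercept a0 must be <= 0 (pure water ~ 0 MPa)")
        lo, hi = self.valid_range
        grid = np.linspace(lo, hi, 1000)
        slope = 2 * a2 * grid + a1
        if not np.all(slope < 0):
            raise ValueError(
                "calibration must be strictly decreasing on its valid range"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coeffs": list(self.coeffs),
            "valid_range": list(self.valid_range),
            "temperature_C": self.temperature_C,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PEGCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            coeffs=tuple(d["coeffs"]),
            valid_range=tuple(d["valid_range"]),
            temperature_C=d["temperature_C"],
        )


DEFAULT_CALIBRATION = PEGCalibration(coeffs=(-11.517, -1.0508, -0.0342))


def psi_from_conc(cal: PEGCalibration, conc: float) -> float:
    """Osmotic potential (MPa) of a PEG solution of concentration conc (g/g)."""
    lo, hi = cal.valid_range
    if not (lo <= conc <= hi):
        raise OutOfRange(f"concentration {conc} outside calibrated [{lo}, {hi}]")
    if conc > VISCOSITY_WARNING_CONC:
        warnings.warn(
            f"concentration {conc} g/g exceeds {VISCOSITY_WARNING_CONC}: "
            "solution viscosity may mechanically impede rolling",
            stacklevel=2,
        )
    return float(np.polyval(cal.coeffs, conc))


def conc_from_psi(cal: PEGCalibration, psi: float) -> float:
    """Invert the calibration: concentration (g/g) giving potential psi (MPa).

    The quadratic is strictly decreasing on the valid range, so the root is
    unique there; the round trip through :func:`psi_from_conc` is exact to
    numerical precision.
    """
    a2, a1, a0 = cal.coeffs
    lo, hi = cal.valid_range
    roots = np.roots([a2, a1, a0 - psi])
    real = roots[np.abs(roots.imag) < 1e-12].real
    eps = 1e-9
    in_range = [r for r in real if lo - eps <= r <= hi + eps]
    if not in_range:
        raise NoRootInRange(
            f"potential {psi} MPa unreachable on concentration range [{lo}, {hi}]"
        )
    return float(np.clip(min(in_range, key=lambda r: abs(r - lo)), lo, hi))


def fit_calibration(
    table: Sequence[tuple[float, float]], degree: int = 2
) -> PEGCalibration:
    """Least-squares polynomial calibration from (conc, psi) measurements.

    Requires at least degree + 2 points with distinct concentrations, so
    there is at least one residual degree of freedom for diagnostics. The
    returned calibration carries residuals and RMSE in ``diagnostics``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("table must be a sequence of (conc, psi) pairs")
    conc, psi = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < degree + 2:
        raise RankDeficient(
            f"need at least {degree + 2} distinct concentrations, "
            f"got {len(np.unique(conc))}"
        )
    coeffs = np.polyfit(conc, psi, degree)
    fitted = np.polyval(coeffs, conc)
    resid = psi - fitted
    diagnostics = {
        "residuals": resid.tolist(),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n_points": len(conc),
    }
    lo, hi = float(conc.min()), float(conc.max())
    return PEGCalibration(
        coeffs=tuple(float(c) for c in np.pad(coeffs, (3 - len(coeffs), 0))),
        valid_range=(min(lo, 0.0), hi),
        diagnostics=diagnostics,
    )
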