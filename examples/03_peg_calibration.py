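"""PEG 3350 osmoticum calibration: concentration <-> osmotic potential.

Shows the default quadratic calibration (20 degrees C), its inversion for
experiment planning, and refitting from a measurement table.
"""

import numpy as np

from leafroll import (
    DEFAULT_CALIBRATION,
    TREATMENT_POTENTIALS_MPA,
    conc_from_psi,
    fit_calibration,
    psi_from_conc,
)

print("concentration (g/g) -> osmotic potential (MPa):")
for c in (0.0, 0.10, 0.20, 0.30, 0.45):
    print(f"  {c:4.2f} -> {psi_from_conc(DEFAULT_CALIBRATION, c):+7.4f}")

print("\nconcentrations needed for the standard dehydration series:")
for psi in TREATMENT_POTENTIALS_MPA:
    print(f"  {psi:+5.2f} MPa -> {conc_from_psi(DEFAULT_CALIBRATION, psi):.4f} g/g")

# refit from a synthetic psychrometer table (noise-free here)
conc = np.linspace(0.0, 0.5, 11)
psi = np.polyval(DEFAULT_CALIBRATION.coeffs, conc)
cal = fit_calibration(list(zip(conc, psi)))
print(f"\nrefit coefficients: {tuple(round(a, 4) for a in cal.coeffs)}")
print(f"refit RMSE: {cal.diagnostics['rmse']:.2e} MPa")
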