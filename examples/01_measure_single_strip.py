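"""Measure rolled-upness of a single synthetic leaf strip.

Builds a semicircular cross-section of radius 2 mm (true curvature
0.5 mm^-1, true length 2*pi = 6.283 mm), fits the smoothing spline at the
default trace of 10, and prints the two rolling indices.
"""

import numpy as np

from leafroll import ShapeSpec, make_shape, measure_strip

section = make_shape(
    ShapeSpec(kind="arc", length=2 * np.pi, kappa=0.5, n_points=35)
)
m = measure_strip(section)

print(f"mean curvature : {m['mean_curvature_mm']:+.4f} mm^-1   (true +0.5000)")
print(f"strip length   : {m['strip_length_mm']:.4f} mm       (true {2*np.pi:.4f})")
print(f"hull diameter  : {m['hull_diameter_mm']:.4f} mm       (true 4.0000)")
print(f"log index      : {m['log_index']:.4f}          (true ln(pi/2) = {np.log(np.pi/2):.4f})")
print()
print("Positive mean curvature means the section curls toward the adaxial")
print("(upper) leaf surface; the log index ln(length/diameter) grows as the")
print("strip rolls up and its convex hull tightens.")
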