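"""Predict misregistration tolerance from the phase-length map alone.

Accumulates the straight-ray phase through two aberrators that differ only
in lateral feature scale, converts to phasors, and cross-correlates a
beam-sized circular patch with the full pattern.  Media whose phase
pattern stays correlated over larger areas tolerate larger registration
errors.
"""

import numpy as np

import hasim as h

array = h.build_spherical_array(16, aperture_diameter=0.05, focal_length=0.055,
                                frequency=1.0e6)
grid = h.centered_grid((64, 64, 80), (5e-4, 5e-4, 5e-4), z0=0.035)
radius = h.beam_radius_at_plane(array, grid.origin[2])
print(f"beam radius at the model entry plane: {radius*1e3:.1f} mm")
radius = min(radius, 6e-3)

for scale in (2e-3, 6e-3):
    model, _ = h.generate_aberrator(seed=21, grid=grid, feature_scale=scale)
    plm = h.phase_length_map(model, 1.0e6)
    result = h.phasor_autocorrelation(plm, radius, fractions=(0.25, 0.5, 0.75))
    areas = {f: round(a, 1) for f, a in result.contour_areas_mm2.items()}
    print(f"feature scale {scale*1e3:.0f} mm -> contour areas (mm^2): {areas}")

print(
    "-> the broader-feature plate correlates over a much larger area at "
    "the 50 % level: its conjugate phases keep working under larger shifts."
)
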