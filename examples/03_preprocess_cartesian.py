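"""From a Cartesian fundus thickness map to a registered polar map.

Applies magnification correction (axial-length dependent transverse
rescale) and resamples 21 rings in the canonical orientation: nasal
midline at 0 deg, temporal maculopapillary axis at 180 deg, superior
hemisphere in (0, 180) for either eye.
"""

import numpy as np

from fiberflux import SyntheticEyeSpec, generate_eye, magnification_correct, resample_polar

eye = generate_eye(SyntheticEyeSpec(seed=3, noise_sd_um=0.0, axial_length=26.28,
                                    mpa_angle=6.8))
cart = eye.cartesian_thickness
print(f"nominal pixel pitch: {cart.pitch*1000:.2f} um "
      f"(axial length {eye.meta.axial_length} mm)")

corrected, meta = magnification_correct(cart, eye.meta)
print(f"magnification-corrected pitch: {corrected.pitch*1000:.2f} um, "
      f"MPA angle {meta.mpa_angle:.1f} deg")

polar = resample_polar(corrected, meta)
diff = np.abs(polar.values - eye.polar_thickness.values)
print(f"rings: {polar.radii[0]}..{polar.radii[-1]} mm x {polar.n_theta} angles")
print(f"round-trip vs the generator's polar truth: mean |dT| {diff.mean():.3f} um "
      f"(bilinear interpolation error)")
# The double-hump profile: thickest at the arcuate bundles
prof = polar.values.mean(axis=0)
peak = polar.theta[np.argmax(prof)]
print(f"thickest angular position: {peak:.0f} deg (superotemporal bundle)")
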