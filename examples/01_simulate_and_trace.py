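"""Generate a synthetic eye and recover its nerve fiber trajectories.

Builds a noise-free flux-conserving eye, runs the iterative equal-flux
tracer and compares the recovered track boundaries with the generator's
ground truth.
"""

import numpy as np

from fiberflux import (
    SyntheticEyeSpec, generate_eye, trace_iterate, flux_density, ring_flux,
)

eye = generate_eye(SyntheticEyeSpec(seed=1, macular_termination=False,
                                    noise_sd_um=0.0))
res = trace_iterate(eye.polar_thickness)

print(f"converged: {res.converged} after {res.n_iterations} iterations")
print("per-iteration max |d beta| (deg):",
      " ".join(f"{d:.3f}" for d in res.deltas))

rf = ring_flux(flux_density(eye.polar_thickness, res.skew))
print(f"skew-corrected ring flux: {rf.mean():.4f} mm^2, CV {100*rf.std()/rf.mean():.4f} %")

radii = eye.polar_thickness.radii
err = np.abs(res.trajectory.boundary_angles(radii)
             - eye.truth_trajectory.boundary_angles(radii))
print(f"boundary recovery error: median {np.median(err):.3f} deg, "
      f"max {err.max():.3f} deg")
# The tracer sees only the thickness map; agreement with the generator's
# hidden trajectories shows flux conservation alone pins down the fiber
# courses.
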