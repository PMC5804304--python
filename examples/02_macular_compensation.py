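"""Ganglion-cell compensation on the macular side.

Temporal-track flux decays outward because fibers terminate on macular
retinal ganglion cells; the compensation coefficient gamma restores a
conserved quantity.  This script shows the decay, the gamma map and the
restored conservation.
"""

import numpy as np

from fiberflux import (
    RgcDensityModel, SyntheticEyeSpec, compensation_map, default_family,
    flux_density, generate_eye, ring_flux,
)

eye = generate_eye(SyntheticEyeSpec(seed=2, macular_termination=True,
                                    noise_sd_um=0.0))
pm = eye.polar_thickness

uncomp = ring_flux(flux_density(pm, eye.truth_cos_beta))
print(f"uncompensated ring flux: {uncomp[0]:.4f} mm^2 at r=1.5 mm -> "
      f"{uncomp[-1]:.4f} mm^2 at r=3.5 mm "
      f"({100*(1-uncomp[-1]/uncomp[0]):.1f} % lost to macular RGC terminations)")

gamma = compensation_map(default_family(), RgcDensityModel(), pm.radii, pm.n_theta)
print(f"gamma range: 1.0 (outside the 110-270 deg zone) to {gamma.values.max():.3f}")

comp = ring_flux(flux_density(pm, eye.truth_cos_beta, gamma))
print(f"compensated ring flux CV across 21 rings: {100*comp.std()/comp.mean():.2g} %")
# Conservation is restored because the compensation integrates the same
# parametric RGC density along the same reference trajectories that
# generated the flux loss.
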