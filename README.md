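# fiberflux

Nerve fiber flux (NFF) analysis of wide-field peripapillary OCT scans.

Retinal nerve fibers converge on the optic disc along arcuate courses, so a
sampling circle around the disc cuts them at a skew angle β that inflates
the apparent nerve fiber layer (NFL) cross-section, and the same angular
position samples *different* fibers at different circle radii.  `fiberflux`
treats the fibers as field lines: the **nerve fiber flux**

```
dΦ(r, θ) = T(r, θ) · γ(r, θ) · cos β(r, θ) · r · dθ
```

(the perpendicular fiber cross-sectional area crossing a ring element, with
`T` the NFL thickness and `γ` a ganglion-cell compensation on the macular
side) is conserved along a fiber bundle.  Starting from β = 0, the package
iteratively divides each ring of a polar-resampled thickness map into 64
equal-flux tracks per eye (32 per hemisphere, split at the nasal horizontal
midline and the temporal maculopapillary axis), constrains each track
boundary to the arcuate model

```
φₙ(r) = aₙ + bₙ (r − r₀)^cₙ ,   r₀ = 0.85 mm,
```

rebuilds the cos β map from the fitted arcs, and repeats until β changes by
less than 0.01° anywhere.  Healthy-eye trajectories are averaged into a
normative template; any test eye is then quantified as NFF per track and
per Garway-Heath-style sector (PM, IA, OA, TF per hemisphere, anchored on
the 1.7-mm circle and propagated outward along the template trajectories),
with fraction-deviation maps and a 5th-percentile normative cutoff for
focal-defect detection.

The package is aimed at OCT image-analysis researchers: it operates on
gridded NFL thickness maps (CSV + JSON sidecar) rather than vendor raw
data, and ships a synthetic-eye generator with exact ground truth so the
whole pipeline is testable without any scan data.

## Worked example

```python
import numpy as np
from fiberflux import (SyntheticEyeSpec, generate_eye, default_family,
                       RgcDensityModel, compensation_map, trace_iterate,
                       flux_density, ring_flux)

eye = generate_eye(SyntheticEyeSpec(seed=1, noise_sd_um=0.0))     # synthetic eye
gamma = compensation_map(default_family(), RgcDensityModel(),
                         eye.polar_thickness.radii, 1024)          # γ map
res = trace_iterate(eye.polar_thickness, gamma=gamma)              # trace fibers
print("converged:", res.converged, "after", res.n_iterations, "iterations")
rf = ring_flux(flux_density(eye.polar_thickness, res.skew, gamma))
print("ring flux CV: %.4f %%" % (100 * rf.std() / rf.mean()))
err = np.abs(res.trajectory.boundary_angles(eye.polar_thickness.radii)
             - eye.truth_trajectory.boundary_angles(eye.polar_thickness.radii))
print("median boundary error: %.3f deg" % np.median(err))
```

prints

```
converged: True after 16 iterations
ring flux CV: 0.0006 %
median boundary error: 0.015 deg
```

i.e. the tracer converges, the compensated flux is conserved across all 21
rings (radii 1.5–3.5 mm) to a fraction of a percent, and the recovered
track boundaries match the generator's ground-truth trajectories to
hundredths of a degree.  The scripts in `examples/` walk through each
capability (simulation, preprocessing, tracing, compensation, template
building, sector analysis) the same way; `nff --help` exposes the pipeline
as a command line.

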