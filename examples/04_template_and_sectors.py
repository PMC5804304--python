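"""Normative template, sector propagation and defect detection.

Traces a small healthy cohort, averages the trajectories into a template,
propagates the 8 anchor-circle sector demarcations outward, and classifies
a glaucomatous eye with an arcuate wedge defect against the normative 5th
percentile.
"""

from dataclasses import replace

import numpy as np

from fiberflux import (
    RgcDensityModel, SectorScheme, SyntheticEyeSpec, average_trajectories,
    build_normative_flux, classify_sectors, compensation_map, default_family,
    generate_eye, nff_per_track, propagate_sectors, trace_iterate,
)

n_eyes = 8  # small demo cohort; the test-suite uses 24
base = SyntheticEyeSpec(seed=0, jitter_sd_deg=5.0, noise_sd_um=2.0)
cohort = [generate_eye(replace(base, seed=100 + i)) for i in range(n_eyes)]

gamma = compensation_map(default_family(), RgcDensityModel(),
                         cohort[0].polar_thickness.radii, 1024)
traces = [trace_iterate(e.polar_thickness, gamma=gamma) for e in cohort]
template = average_trajectories([t.trajectory for t in traces])
print(f"traced {n_eyes} healthy eyes; "
      f"boundary SD at r=3.5 mm: {template.outer_sd_summary().max():.1f} deg max")

scheme = SectorScheme()
geometry = propagate_sectors(template, scheme)
tables = [nff_per_track(e.polar_thickness, template, geometry) for e in cohort]
normative = build_normative_flux(tables)
print(f"normative overall NFF: {normative.overall_mean:.3f} mm^2")

defect_eye = generate_eye(SyntheticEyeSpec(seed=999, noise_sd_um=2.0,
                                           defects=[(12, 18, 0.45)]))
table = nff_per_track(defect_eye.polar_thickness, template, geometry)
result = classify_sectors(table, normative)
for label, s in result["sectors"].items():
    flag = "ABNORMAL" if s["abnormal"] else "normal  "
    print(f"  {label:7s} {flag} flux {s['flux_mm2']:.4f} mm^2 "
          f"({s['deviation_percent']:+5.1f} % vs normative mean)")
# The wedge (tracks 12-18, 55 % loss) lands in the superior arcuate
# sectors, which fall below the 5 % normative cutoff; other sectors stay
# within normal limits.
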