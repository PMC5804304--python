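# Methods

## The model

Retinal ganglion cell (RGC) axons run from their somata to the optic disc
in bundles whose perpendicular cross-sectional area (axons plus associated
glia) is approximately conserved along their course.  Treating fibers as
field lines, RGCs as sources and the disc as a sink, the **nerve fiber
flux** crossing an element of a disc-centred sampling circle is

    dΦ(r, θ) = T(r, θ) · γ(r, θ) · cos β(r, θ) · r · dθ        [mm²]

where `T` is NFL thickness (stored in µm, converted to mm), `β` the skew
angle between the fiber course and the radial direction (an oblique cut
inflates the apparent cross-section by 1/cos β), and `γ ≥ 1` compensates
for fibers that terminate on macular RGCs (below).  Absent sources, the
flux through any closed contour around the disc is constant — the
two-dimensional analogue of the flux theorem for a divergence-free field.

### Trajectory tracing

Each hemisphere of each sampling ring is divided into 32 tracks of equal
flux; following the division boundaries across rings yields the fiber
trajectories.  Since `cos β` depends on the trajectories, the solution is a
fixed point, found by iteration:

1. start with β = 0 everywhere;
2. divide every ring's flux-per-degree profile into 32 equal parts per
   hemisphere (piecewise-linear density between samples; its piecewise-
   quadratic cumulative is inverted exactly; a quantile landing on a
   zero-density plateau is placed at the plateau midpoint);
3. fit each of the 62 inner boundary lines to the arcuate model
   `φ(r) = a + b (r − r₀)^c`, `r₀ = 0.85 mm` (the anchor-circle radius);
   the two hemisphere borders are fixed radial lines at 0° and 180°;
4. rebuild the skew map: on each ring, β is computed analytically on the
   track centrelines (`tan β = r·dφ/dr`, with `dφ/dr` the mean of the two
   border derivatives) and interpolated linearly in angle within each
   hemisphere, clamped at the borders;
5. recompute the flux density with the new cos β and repeat until
   `max |Δβ| < 0.01°` over the whole (ring × angle) grid, up to 50
   iterations, with a divergence guard (three consecutive increases stop
   the loop with a flag).

β is differentiated analytically from the fitted model rather than by
ring-to-ring finite differences: the arcuate constraint makes the
derivative exact and noise-robust.  The iteration count is ~15–25 on
realistic synthetic maps; a purely radial map converges at the first
change check (iteration 2).

The arcuate fit profiles the exponent out (the problem is linear in
`(a, b)` for fixed `c`): a 25-point log-spaced sweep over `c ∈ (0.05, 5]`,
refined by bounded 1-D minimisation (`xatol = 1e-12`).  Constant samples
leave `c` unidentifiable and are reported as `b = 0, c = 1` with a flag.
Noise-free samples from the model family are recovered to ~1e-8.  Under
angular noise the exponent fit is ill-conditioned — at σ = 0.5° and 21
radii the Cramér–Rao bound on the anchor angle `a` is ≈ 0.75° for a
typical arcuate shape — so per-draw intercept errors of that order are
expected; the estimator is unbiased (Monte-Carlo mean within 0.5°).

### Hemisphere registration

All maps share one angular convention: 0° = nasal horizontal midline,
180° = temporal maculopapillary axis (MPA), superior hemisphere (0°, 180°),
with angles increasing counterclockwise in right eyes and clockwise in left
eyes so a left eye and its mirrored twin analyse identically.  The nasal
border is horizontal while the MPA is tilted by the MPA angle `m`
(fovea→disc axis vs horizontal; positive when the fovea sits inferior), so
registration is a per-hemisphere piecewise-linear angular remap: the
superior physical arc `[0°, 180° + m]` maps onto `[0°, 180°]` and the
inferior arc onto `[180°, 360°]`.  For `m = 0` this is the identity; at
typical `m ≈ 7°` the local angular distortion is < 4 %.  A rigid whole-map
rotation cannot put both borders at exactly 0°/180°, which the hemisphere
confinement requires (it stops segmentation and centration errors from
propagating across the midline).

### Preprocessing

ILM tilt correction first (`T' = T·cos α`, `cos α = (1+|∇h|²)^(-1/2)` from
the elevation gradient by central differences — a per-pixel optical
correction), then optical magnification (transverse pitch and all image-
derived coordinates scaled by `s = (AL − 1.82)/(AL_ref − 1.82)`, a
Bennett-style factor with configurable reference `AL_ref = 24.46 mm`), then
polar resampling: 21 rings at radii 1.5–3.5 mm (uniform 0.1 mm spacing;
only the count and range are canonical, the uniform spacing is our choice)
× 1024 angular samples, bilinear interpolation, registration folded into
the sampling directions.

### Macular compensation (γ)

Temporally, fibers terminate on macular RGCs and flux decays.  Assuming
the flux reduction is proportional to the RGC count integrated along the
track, and noting that a fiber crosses disc-radius `r` iff its soma lies
beyond `r` along the track:

    Φ(r) = Φ(r_in) · (1 − L(r)/L∞),     γ(r) = 1 / (1 − L(r)/L∞)

with `L(r)` the RGC count in the track footprint (density × width × arc
element along the centreline) from the innermost ring to `r`, and `L∞` the
track's total fiber complement.  `L∞` extends the footprint integral to a
beyond-map allowance radius (default 8 mm; the arcuate model is trusted to
4 mm, beyond which the footprint continues radially with frozen angle and
width) and divides by `(1 − p)` where `p = 0.55` is the assumed share of
each temporal track's fibers originating in peripheral retina outside the
allowance — sparse density over a vast catchment.  `p` caps the
compensation at γ ≈ 1.3 at the outer rings, consistent with compensation
being significant only in the outer temporal circles; it is configurable.
γ is computed only for angular positions 110°–270° and set to exactly 1
elsewhere (hard step, matching the published zone convention; RGC density
is negligible nasally).

The RGC density is a parametric, radially symmetric, foveally peaked
profile rather than digitized literature data (keeps the artifact
download-free): zero inside a 0.15-mm foveal pit, sin² rise to a peak ring
at 1.7 mm eccentricity (default peak 35 000 cells/mm², optional total-count
normalization), exponential decay with a 1.5-mm scale outside (< 1 % of
peak at 10 mm).  γ is derived once from the package's canonical reference
trajectory (the role a literature trajectory model plays in the published
procedure) and used as a fixed map when tracing healthy eyes; diseased
eyes are never compensated (their RGC distribution is unknown) and never
traced — they receive the normative template.

### Template, sectors, classification

Healthy-eye trajectories are averaged boundary-wise on angular positions
at the shared radii and refit to the arcuate model (parameter-space means
distort trajectories because `(a, b, c)` are non-linearly coupled);
per-boundary angular SD at each radius is retained, and the population
cos β map derives from the averaged trajectories.  The model extrapolates
the template inward to the anchor circle and outward to 4.0 mm; beyond
that, individual deviation is amplified and evaluation is refused.

Eight sectors (papillomacular, inner arcuate, outer arcuate,
temporal-field per hemisphere) are anchored on the 1.7-mm-diameter circle
and propagated outward along the template: each demarcation follows an
arcuate curve anchored at its angle with `(b, c)` interpolated from the
flanking template boundaries.  The canonical demarcation angles are not
universal constants; the defaults (0/50/95/140/180/220/265/310° in the
canonical frame) adapt the Garway-Heath disc-rim spans and ship in config;
every report records the anchors used.

A test eye's NFF per track integrates `T · cos β_template · r` in angle
between template boundaries on each ring (bin-consistent cumulative:
samples are bin averages, the cumulative is linear within bins and exact
at bin edges).  The per-track summary is the **mean** over the 21 rings —
each ring estimates the same conserved flux; summing rings is available by
config.  Sector flux sums member tracks, so sectors partition the overall
NFF exactly.  A sector is abnormal iff its flux falls strictly below the
cohort's empirical 5th percentile (linear-interpolated order statistic,
preferred over mean − 1.645·SD for small cohorts; both conventions are a
config switch).  Fraction-deviation maps are `100·(test − ref)/ref` with
zero-reference entries masked.

## The synthetic-data generator

The generator is the oracle for everything else, so its construction is
exact where the pipeline's contracts are exact:

* **Trajectory family** — 64 boundary anchors from a double-hump angular
  width density (von-Mises bumps at 120°/240°, height 2.2, κ ≈ 5.25);
  curvature `b(a)` peaks (4°/mm^c) in the arcuate bundles at 115° from the
  nasal midline and vanishes nasally; exponent `c(a) ∈ [1.2, 1.8]`.
  Narrowest tracks ≈ 2.2° at r = 3.5 mm superotemporally; maximum skew
  β ≈ 44° temporally at the outer rings.
* **Conservation by construction** — per-bin flux is integrated exactly
  from piecewise-constant per-track densities (equal per-track flux,
  default 1.5 mm² overall), so ring totals match to machine precision.
  Smoothing (periodic Gaussian, 1.4° FWHM) is applied to the flux density
  (sum-preserving) *before* the termination and defect factors; thickness
  is then `T = (dΦ/dθ)/(γ_true⁻¹ ... r cos β)` with the same skew-map code
  the tracer uses.
* **Macular termination** — the same `track_termination_fractions`
  routine that builds γ, guaranteeing the compensation self-consistency
  property is a test of the derivation, not of shared bugs in disguise:
  the γ-compensated generated flux is constant to ~1e-14 on matching
  geometry.
* **Inter-eye jitter** — a smooth low-order sine field in anchor angle
  (vanishing at the hemisphere borders) perturbs each boundary's
  curvature `b` so the boundary shifts by the field value (pointwise SD =
  5° by default) at the outermost ring and not at all at the anchor
  circle — individual trajectory variability grows with radial distance
  from the disc, which is why sector schemes anchor at the disc rim.
  Draws that would cross boundaries are rejected and redrawn.
* **Wedge defects** — sharp multiplicative loss (scale ∈ (0, 1]) between
  two true track boundaries, applied after smoothing.  A sub-bin edge
  cannot be split correctly by any bin-average reader, so edges are
  rasterized conservatively: the edge bin's allocation deficit moves into
  its neighbour such that the bin-linear cumulative is exact at the cut
  angle and within-wedge totals scale exactly (a one-bin rim, like the
  steep wall of a real defect).  Track summaries then scale exactly by
  construction against the true boundaries, and within ~0.6 % against a
  traced template.
* **Noise** — additive Gaussian thickness noise (default SD 2 µm),
  clipped at zero, added last.
* **Rendering** — the polar truth (extended one ring inward/outward) is
  rendered onto an 8 × 8 mm Cartesian grid (default 320², 25 µm pitch)
  through the inverse registration warp, with the nominal pixel pitch
  mis-scaled by the magnification factor so preprocessing has something to
  undo.  Default cohort: 24 healthy + 10 glaucomatous eyes; per-eye MPA
  angles drawn N(6.8°, 3.1°).

What the generator does **not** emulate: vessel shadows and speckle,
segmentation failures, disc-size variation, real RGC density asymmetries
(the parametric profile is radially symmetric about the fovea), and any
deviation of real fiber anatomy from the arcuate model family — the
generator's trajectories are exactly of the form the tracer fits, so
passing recovery tests shows the algorithm is correct and well-conditioned,
not that real fibers follow the model.

## Numerical choices and problem sizes

* Angular grid 1024 samples (0.3516°); samples are bin averages for
  integration (periodic rectangle rule is exact) and point values for
  interpolation.
* Convergence tolerance 0.01° on the full β grid; max 50 iterations.
* Test-suite and acceptance problem sizes: 20 eyes for trajectory
  recovery (noise-free and 2 µm noise), 24 jittered eyes for the
  normative template, 100 random profiles for the division oracle, 100
  Monte-Carlo draws for the noisy fit — sizes at which the measured
  statistics are stable while a full run stays around a minute.
* The equal-flux inversion solves the piecewise-quadratic cumulative in
  closed form (stable root); agreement with a dense brute-force inversion
  is ~1e-6 degrees.
* Boundary-recovery error on noise-free eyes is dominated by the
  smoothing kernel moving flux across density steps (≈ 0.4·σ·Δd/d per
  edge, ~0.1–0.2° at the sharpest width transitions); median error is
  ~0.02–0.09°.

## Known limitations

* The γ functional form is a re-derivation from the stated conservation
  principle; the peripheral fiber share `p` and the allowance radius are
  modeling choices, not measured anatomy.
* The template-recovery bound (median within 1.5° of family truth at
  r = 3.5 mm from 24 eyes at 5° jitter) is a statistical test with
  per-boundary SE ≈ 5/√24 ≈ 1.02°; occasional cohort draws exceed it.
* Glaucomatous eyes are quantified with the healthy template under the
  assumption that disease does not reroute surviving fibers.
* Extrapolation beyond 4 mm radius is refused rather than attempted.
* Registration assumes accurate disc and fovea centres; their estimation
  is upstream of this package.
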