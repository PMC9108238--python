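# Methods

This note documents the models, conventions and numerical choices behind
`aortamorph`, and what the phantom-based validation does and does not show.

## Geometry conventions

Geometry lives in millimetres on disk (STL, CSV tables) and in the mesh
containers; hemodynamic formulas convert to SI internally (areas mm² → m²,
FBP also reported in cm). Vertex indexing is 0-based everywhere. Surfaces
are welded on load (tolerance 1e−6 mm), degenerate and duplicate facets are
dropped, and orientation is fixed so the signed volume is positive. A mesh
that stays non-manifold after welding is flagged, not rejected.

## Registration

Point-to-point ICP with the Kabsch/Umeyama closed-form rigid fit (SVD with
reflection correction, no scaling). Initialization aligns centroids and
principal axes; the four proper-rotation sign combinations are scored by
starting RMS and ties resolved in lexicographic flip order, plus a plain
centroid-shift candidate. Convergence when the RMS improvement falls below
`tol` (default 1e−6 mm) or after `max_iter` (200). Sources above 50 000
points are stride-subsampled for correspondence; the reported RMS is always
over all points. Degenerate (coplanar/collinear) sources are rejected — the
rotation is not identifiable there.

Two identifiability caveats that the tests respect: a circular cylinder is
invariant under rotations about its axis and under a 180° flip, so on such
surfaces only the residual RMS (not the transform parameters) is meaningful;
the composite-arch phantom deliberately uses unequal straight segments
(L and 0.6·L) so transform recovery is well-posed. When the follow-up surface
is additionally grown by δ along its normals, the converged ICP residual RMS
equals δ — the registration has succeeded when the residual matches the
physical growth, not when it vanishes.

## Centerline and slice morphometry

The centerline is extracted by seeded centroid-marching: starting from a
proximal seed, step `step_mm` (default 1 mm) along the current tangent and
re-center at the area centroid of the plane–mesh section perpendicular to it;
two fixed-point refinement passes then re-center every interior point using
central-difference tangents. Endpoints stay anchored during refinement
(tilted planes near an end cap cut into the cap) and refinement moves larger
than one step are rejected as artifacts. The initial direction is chosen
among the seed chord, the local surface-patch axis and the three global
principal axes by the minimal-section-area criterion (the true tube tangent
minimizes the cut), with the sign fixed by a trial step. The method is
deterministic and mesh-only. Branches are handled as separate seeded runs; a
genuinely ambiguous continuation (two comparable contours) raises an error
asking for an intermediate seed.

Slices are placed from the proximal end inclusive every `interval_mm`
(default 1.0 mm, endpoints inclusive; a final partial interval is dropped);
planes at the exact ends are nudged 1e−3 mm inward so they do not coincide
with cap facets. Contours not enclosing the centerline point are kept but
labeled `secondary` (e.g. the FL when slicing a combined surface).

Per-slice metrics: area by the planar shoelace formula; circumference as the
polygon perimeter; equivalent diameter `2√(A/π)`; **transverse diameter** as
the maximum Feret (caliper) diameter; **longitudinal diameter** as the extent
perpendicular to the transverse direction; aspect ratio transverse /
longitudinal (≥ 1 by construction). These diameter conventions are stated
prominently because other conventions exist (e.g. axis-aligned extents);
users comparing against other toolchains should check them first.

Curvature is the Menger (circumscribed-circle) curvature of consecutive
point triples after a moving-average smoothing of the polyline (default
window 5 mm), which suppresses mesh-faceting noise; points whose smoothing
window overlaps the padded ends copy the nearest cleanly-supported interior
value. Tortuosity is `1 − d/l`, dimensionless, in [0, 1).

## Hemodynamic indicators

TAWSS, OSI and RRT use the standard literature definitions (stated in the
README). Cycle integrals use the trapezoidal rule with a periodic wrap: the
sample at t = T is the first sample again, matching fields discretized at 50
uniform steps per cycle (the default temporal resolution; cardiac periods
default to 60/55 s pre- and 60/85 s post-treatment). RRT where the cycle-mean
WSS vector vanishes (OSI = 0.5 or TAWSS = 0) is +∞, and denominators at
round-off scale (≤1e−12 relative) are treated as vanishing.

Slice-averaged pressure ("net pressure" per slice) is the unweighted mean of
the pressure sampled where the slicing plane cuts mesh edges (linear
interpolation along each cut edge, i.e. inverse-distance weighting of the
edge endpoints; vertices lying exactly in the plane contribute directly),
restricted to the neighbourhood of the slice's primary contour, then
time-averaged. The choice of vertex-mean over area-weighted mean is a
convention; it does not move the FBP, which depends only on the sign of
LPD. The FBP is the most proximal sign change of LPD located by linear
interpolation between bracketing stations; an exactly-zero station is itself
the FBP; no sign change returns the sentinel `None` ("beyond the dissected
region").

Energy loss treats each open boundary as a plug (area-uniform) velocity
profile — the natural reading of a Doppler maximum-velocity trace; a
`velocity_shape_factor` (default 1.0) can rescale the trace to a mean
velocity if a profile assumption is preferred. `EL = Σ_in⟨TP·Q⟩ −
Σ_out⟨TP·Q⟩` with `TP = ½ρū² + P̄` and `Q = ū·A`; ρ defaults to 1044 kg/m³
(dynamic viscosity 0.00365 Pa·s is carried as a configuration constant).
A negative EL is returned with a warning flag, since it usually indicates a
mislabeled boundary. Waveform resampling uses a periodic cubic spline; at
typical Doppler sampling densities its error is negligible against the
traces' amplitude, where linear interpolation is not.

## Evolution fields and sign conventions

Correspondence from the reference surface A to the follow-up B casts rays
from every A-vertex along ± its outward normal (analytic normals when the
surface came from the phantom generator, area-weighted otherwise) and takes
the nearest intersection within a 10 mm cutoff; the signed distance is
positive when B lies outside A. Ray casting rather than closest-point is the
primary match because closest-point underestimates oblique growth; vertices
without a hit fall back to closest-point (flagged, excluded from area
ratios), and more than 20% fallbacks flags poor alignment. Field values on B
are sampled at matched points by barycentric interpolation.

ΔX supports two conventions: `as_printed` (Δ = X_A − X_B,
earlier-minus-later) and the default `as_described` (Δ = X_B − X_A), under
which a parameter that decreased over follow-up gives negative Δ and hence
dominant AR_N — the usual clinical reading. Area ratios assign each triangle
by the sign of its mean ΔX; exactly-zero triangles count toward AR_P so
AR_P + AR_N = 1 holds identically.

## The phantom suite

Phantoms are lofted tubes (64 circumferential vertices, ~1 axial ring per
mm by default — about 1% analytic agreement at desk scale): straight tube,
torus segment, composite arch (straight L → arc → straight 0.6·L), and a
straight dissected segment whose TL/FL are the two circular segments cut by
a flat chord septum, the chord offset solved so the TL area fraction equals
`septum_fraction` exactly. Tears are carried as sorted arc-length
annotations. Fields are uniform, axial-linear, or cosine-pulsatile
(`base + amplitude·cos(2πt/T + phase)`), so every cycle integral has a
closed form. Deformation ground truth is radial growth along the analytic
normals followed by a known rigid transform.

The two-timepoint "improving" case mirrors a favourable post-stent course:
the lumen grows +0.5 mm, pressures attenuate to 80%, and the WSS loses its
oscillatory component while slightly gaining mean shear (base/amplitude
1.0/1.5 Pa → 1.1/0.3 Pa). The WSS change is deliberately not a uniform
scale-down: OSI is invariant under uniform scaling and RRT rises when TAWSS
falls, so a pure attenuation cannot decrease all four indicators at once;
the chosen waveform change makes TAWSS, OSI, RRT and pressure all decrease,
which is the qualitative pattern of interest. The dissection preset
prescribes TL/FL pressures `2020 − 1.0·z` and `2000 − 0.5·z` Pa, so
LPD = 20 − 0.5·z crosses zero at z = 40 mm; with centerline seeds inset 2 mm
from the ends the pipeline's arc-length FBP is 38 mm, and both numbers are
recorded in the ground-truth JSON.

What the phantoms do **not** emulate: patient-realistic anatomy (taper,
branching, non-circular sections), imaging segmentation noise, solver-grade
flow fields (fields are prescribed, not solved — flow solving is out of
scope), wall compliance, or non-rigid remodeling. Passing the suite
demonstrates that the measurement pipeline is correct on geometry and fields
with known answers; it does not validate CFD fidelity or segmentation.

## Determinism and problem sizes

Everything is deterministic for a fixed config and seed: no timestamps in
outputs, fixed float formatting, sorted JSON keys — re-running a case yields
byte-identical files, which the acceptance suite checks by comparing two
independent runs. Tests and the acceptance script use desk-scale problems
(tubes of 3–6.5 k vertices, 50 timesteps per cycle, 10 noise seeds for ICP),
chosen so the full validation runs in minutes on a single CPU while staying
within ~1% analytic agreement.

## Known limitations

- Centerline extraction assumes a tubular topology between the seeds; it
  does not traverse bifurcations (branches are separate runs).
- The slice-pressure average is vertex-based, not area-weighted; on strongly
  graded fields with very irregular contour sampling the two differ.
- RRT is unbounded near fully oscillatory shear; downstream statistics on
  RRT maps should be robust to +∞ entries (the pipeline excludes non-finite
  triangles from area ratios).
- ICP is rigid only; true anatomical remodeling between timepoints ends up
  in the residual and in the evolution fields, by design.
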