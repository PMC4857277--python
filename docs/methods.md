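# Methods

This note documents the models, numerical choices and limitations behind
`plaqrecon`, in the package's own terms.

## Geometry and morphometry

A cross-section is a set of nested simple polygons (lumen, intima outer,
media outer, adventitia outer borders) plus one or two necrotic-core (NC)
polygons inside the intima ring. Coordinates are Cartesian millimetres;
polygons are stored counter-clockwise; angles are radians counter-clockwise
from +x.

The *lumen center* is the area centroid of the lumen polygon. This is a
modeling choice (alternatives such as the largest inscribed circle exist);
the centroid is robust for mildly eccentric lumens and reproducible.

The NC *front side* is found by casting a ray from the lumen center through
every NC vertex and keeping the vertex only if it is the first intersection
of that ray with the NC boundary — the same geometry that limits light-based
catheters. The *NC angle* is the angular span of the retained vertices (not
of all NC vertices). Site rays sit at 25 % / 50 % / 75 % of that span
(−sidecap / midcap / +sidecap). Along a site ray:

* capT = lumen border → NC front,
* IMT = lumen border → media outer border (intima + media, radially),
* NCt = NC front → NC back (first to last boundary crossing; 0 when the
  backside is absent),
* rNCt = NCt / IMT.

The minimum cap thickness is searched over a dense (0.25°) angular sampling
of the front span, not only at vertex angles. Ray–polygon intersection is
exact per edge, with intersections closer than 1 nm merged and a small
tolerance on the edge parameter so rays through shared vertices cannot slip
between adjacent edges.

## Synthetic plaques

Because the underlying histology is not public, the generator is first-class
code. An idealized section is built in polar form about the lumen centroid:
an (optionally elliptical, area-preserving) lumen; a wall whose
intima–media thickness follows a monotone interpolation of the configured
mid/side values across each NC span, tapering by a half-cosine to a far-wall
baseline over 0.6 rad (compact support, so one plaque never thickens the
opposite wall); an NC band between capT(θ) (quadratic through the mid/side
values) and capT(θ)+NCt(θ), where NCt follows a monotone PCHIP through
(midcap, sidecap, 0-at-edge) knots so the band pinches closed with rounded
ends. An optional narrow Gaussian notch thins the cap away from the site
rays to realize a configured minimum cap thickness without disturbing the
site measurements.

Cohort sampling draws per-NC features from log-normal marginals whose
medians and quartiles are the configured targets (defaults: min cap
0.20 mm with IQR 0.09–0.40, NC angle 54° (35–75°), midcap capT 0.30
(0.13–0.53) mm, IMT 1.05 (0.89–1.29) mm, and rNCt medians 0.40/0.35); a
shared per-artery Gaussian latent (ρ = 0.3 by default) induces within-artery
correlation on the log scale. rNCt is generated from the packaged linear
relation between rNCt and (NC angle, IMT, capT) plus cluster-correlated
noise (SD 0.12) whose latent is *separate* from the covariate latent, so
regression errors stay exogenous. Feasibility requires truncation (IMT ≥
0.6 mm, capT ≤ 0.55·(IMT − media), capT+NCt inside the intima with ≥10 µm
to spare); truncation alone would bias the cohort medians, so the sampler
calibrates a multiplicative cap scale and additive rNCt offsets by bisection
until the post-clamp cohort medians equal the targets. Two NCs occur with
probability 21/52 and are placed in disjoint angular sectors. Everything is
seeded; the truth table records the exact generating values per NC.

What the generator does **not** emulate: irregular histology contour
roughness, non-star-shaped lumens or cores, imaging physics (attenuation,
speckle), longitudinal correlation between neighbouring slices beyond the
artery latent, and calcifications. Tests passing on this cohort show the
pipeline is correct and well-behaved under the printed cohort statistics;
they do not certify accuracy on real histology.

## Backside reconstruction

Inputs are the front polyline, its span, and an rNCt source: the group
medians (0.40/0.35 packaged, or cohort medians computed leave-one-plaque-out
when refitting on an input cohort), the plaque-specific regression, or
injected true values (oracle mode for validation).

* **Back points** lie on the three site rays at radius
  (lumen hit) + capT + rNCt·IMT.
* **Edge arcs**: at each front end vertex E, circle 1 (radius r = 0.14 mm
  per rad of NC angle, configurable) is intersected with the cap — the front
  polyline extended to the lumen along the edge ray; the intersection P
  centers circle 2 (same radius); of the two circle-1×circle-2
  intersections, the center C of the final arc is the one most distant from
  the lumen (exact ties, which occur for perfectly concentric fixtures, are
  broken toward the candidate beyond the NC edge). The arc has radius r,
  extent 30°, starts at E and sweeps toward larger distance from the lumen
  center. If the construction is impossible (very short front), a quarter
  arc centered at E is used and flagged in the result.
* **Closure**: in a frame whose abscissa is the chord between the two arc
  free ends, the unique quartic through the five conditions (two arc ends,
  three back points) is sampled densely; if the assembled polygon
  self-intersects, a quadratic that is exact at the arc ends and
  least-squares through the back points is tried; failing that, the
  operation raises. Degree 4 is a design choice: five interpolation
  conditions determine it uniquely.
* **Clipping**: the closed NC is intersected with the intima region offset
  inward by 10 µm (and, as a guard, any lumen overlap is removed and
  flagged); a clipped result is marked `clipped_to_media`.

Invariants held by construction and enforced in tests: the front polyline is
never altered; NC area is nondecreasing in rNCt before clipping; mirror
symmetric inputs give mirror-symmetric reconstructions; oracle-rNCt round
trips on annular-band fixtures reach SI ≥ 0.9.

## Plaque-specific rNCt regression

Gaussian identity-link GEE with exchangeable working correlation over
arteries: coefficients solve the weighted estimating equations, the
exchangeable α is re-estimated from Pearson residual cross-products each
iteration, and iteration stops when the relative coefficient change is
< 1e-8 (max 100). The coefficient covariance is the **bias-reduced
(Mancl–DeRouen) sandwich** — cluster residuals inflated by (I−H_i)⁻¹ —
because the plain sandwich under-covers the cap-thickness coefficient, whose
heavy-tailed covariate gives single clusters high leverage. r² is the
squared Pearson correlation of fitted vs observed rNCt. The ± sidecap
measurements of one NC enter as two rows sharing the artery cluster.
Predictions outside (0,1) are clamped to [0.01, 0.95]. The packaged
coefficients (natural scale; the conventional presentation is ×1000) are
midcap (0.187, 0.0633 /rad, 0.00029 /µm, −0.00051 /µm) and sidecap (0.175,
0.130, 0.00018, −0.00042), with their published standard errors on the
covariance diagonal. An independent GEE implementation (statsmodels, with
the matching bias-reduced covariance) serves as a test oracle only.

## Finite-element stress analysis

**Meshing.** All contours are star-shaped about the lumen centroid, so the
domain is meshed as a structured polar grid: angular columns (3° near NC
spans and shoulders, 6° elsewhere by default; span endpoints snapped to grid
lines) times radial bands — cap intima (≥7 layers, satisfying the
resolution rule at the thinnest cap by construction), NC, intima behind the
NC, media+adventitia (one material), and a buffer ring (default thickness
50 % of the mean adventitia radius, coarse). Outside an NC span the NC band
collapses to zero thickness and its nodes merge, keeping the triangulation
conforming across the NC edges without constrained Delaunay machinery.
Radial floors (20–30 µm) prevent sliver element rows where an NC pinches out
or was clipped close to the media. Triangles are quadratic (6-node) by
default — far better behaved than linear triangles near incompressibility —
with 3-point quadrature.

**Material model.** Plane strain, total Lagrangian, strain energy
W = C10(Ī₁−3) + (K/2)(J−1)², G = 2·C10, K = 1/D1 (component table: intima
166.7 / 1e−5, media+adventitia 250 / 1e−5, NC 1 / 1e−5, buffer 10 / 0.02 in
kPa and 1/kPa). With D1 = 1e−5 the bulk modulus is 1e5 kPa: effectively
incompressible. The Cauchy stress is the full 3D tensor implied by plane
strain (σ_zz from the out-of-plane stretch constraint), and von Mises is
computed from that full tensor.

**Solution.** Follower pressure on the lumen border (evaluated on the
current configuration; its unsymmetric load stiffness is omitted — with
≤5 kPa load increments Newton still contracts quickly). The material
tangent is a central finite difference of the first Piola–Kirchhoff stress
per quadrature point, assembled sparsely; Newton iterates to a relative
residual < 1e-8 with a backtracking line search that rejects steps inverting
elements, load ramping with adaptive halving, and factorization reuse while
convergence is contracting. Pressure conversions: 100 mmHg = 13.332 kPa,
140 mmHg = 18.666 kPa.

**Verification.** The solver matches the thick-walled-cylinder (plane
strain) closed form within 2 % at element centroids on a homogeneous ring;
reactions on the fixed boundary balance the (zero-resultant) closed-loop
pressure load; von Mises is objective under rigid rotation; displacements
scale inversely with stiffness in the small-strain limit; and PCS changes
< 2 % between the coarse and default mesh profiles.

**Prestress.** The imaged geometry corresponds to the 100 mmHg fixation
pressure, so an unloaded configuration X is recovered by the backward
incremental fixed point X ← X − α(x(X) − x*), warm-started between outer
iterations, with adaptive under-relaxation (α halved on error growth, floor
0.05) and back-off toward the last solvable estimate when an inner solve
fails; convergence is max |x(X) − x*| < 1 µm (≤50 outer iterations). For a
small minority of extreme geometries (minimum cap below ~80 µm combined
with a strongly over-estimated NC) the fixed point stalls around 10 µm and
the operation raises; the pipeline records such sections in its failure
table rather than silently dropping them.

**Peak cap stress.** PCS is the maximum element von Mises stress over the
cap (intima in front of the NC, within the NC angular span) and the
shoulders (intima within 15° beyond either span end), with its element
centroid location (reference frame) and region label.

## Pipeline and evaluation

Per NC: characterize → remove backside → reconstruct (group-average,
plaque-specific, and optionally oracle) → SI and ΔA% vs ground truth →
ground-truth and per-variant FE solves (the ground-truth solve is shared by
both NCs of a section) → PCS, percent differences, and location-shift
classification (colocalization threshold 50 µm — a declared surrogate for
the original visual call, an order of magnitude above the colocalized
distances and below the shifted ones; straight-line distance). Summaries
report medians/IQRs, the linear regression of reconstructed vs ground-truth
PCS, stratification at 300 kPa (the boundary value goes to the high group),
and shift-category counts. Every output row carries the config hash and
seed; identical seeds give byte-identical outputs. When the group averages
or the regression are refit on the input cohort, the group medians are
computed leave-one-plaque-out so no NC informs its own reconstruction.

### Problem sizes used in the shipped experiments

The end-to-end checks run at desk scale as the package's own protocol: the
geometry-ordering experiment uses a ~55-NC seeded cohort without FE; the
stress-ordering experiment uses an 8-section cohort with the coarse mesh
profile (still ≥7 element layers through the cap) and prestress disabled —
all three geometry variants are treated identically, so the ordering of
ground-truth vs reconstruction PCS errors is unaffected, while absolute PCS
values with prestress differ (the 1 µm prestress round trip is verified
separately on a median-geometry model).

## Known limitations

* The mesher requires contours star-shaped about the lumen centroid;
  strongly folded real histology contours would need a general constrained
  triangulator.
* Radial floors perturb NC borders by ≤30 µm where the core pinches out or
  hugs the media.
* Isotropic neo-Hookean tissue only; no fibers, no residual stress beyond
  the pressure prestress, no 3D effects, no fluid–structure interaction.
* Angularly overlapping NCs are rejected; the cohort generator places
  multiple cores in disjoint sectors.
* The backward-incremental fixed point can fail on extreme thin-cap
  geometries (reported, not silently skipped).
* Printed midcap cohort medians are mutually inconsistent (rNCt × IMT ≠
  NCt); the generator targets rNCt, so the emergent midcap NCt median is
  ~0.42 mm.
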