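# Methods

This note documents the models behind `fifplan`: what is simulated, which
choices were open and how they were settled, and what the synthetic results
do and do not say about clinical planning.

## Scope and substrate

The package implements automatic field-in-field (FIF) forward planning for
whole-brain radiotherapy as a closed loop: phantom → opposed-lateral
aperture → equal-weight initial plan → iterative hotspot blocking with
weight re-optimization → evaluation. It deliberately replaces the two
pieces a clinic would take from elsewhere — patient CT data and a treatment
planning system's dose calculation — with transparent stand-ins (a
parametric phantom and a raycast dose model). Everything else (hotspot
definition and detection, block-level selection, subfield MLC shaping,
weight optimization, normalization, stopping rules, metrics) is the
algorithm proper and is implemented in full.

## Coordinate and machine conventions

Patient axes: x right→left, y anterior→posterior, z inferior→superior.
Voxel indices are 0-based; world coordinates refer to voxel centers;
lengths are mm, doses Gy, densities g/cm³. Gantry 0° places the source
anterior; the lateral pair is 90°/270° with a shared isocenter (default:
brain centroid) and SAD 1000 mm. BEV u is the crossplane/leaf-travel axis,
v the superior axis; the opposed beam sees the anatomy mirrored in u, so
opposed apertures are stored as exact u-reflections of each other. MLC
leaves are 5 mm wide at the isocenter plane (configurable), one open
interval per leaf pair; the BEV raster is 2 mm.

## Head phantom

An ellipsoidal body (default semi-axes 75 × 95 × 85 mm) of unit-density
soft tissue, wrapped in a 6 mm bone shell at 1.6 g/cm³, enclosing an
ellipsoidal brain (60 × 75 × 65 mm, ≈ 1225 cm³), with eye spheres and
anterior lens spheres carved out of the soft tissue/bone. These densities
are representative configuration values, not physics claims. A seeded
low-order sinusoidal modulation (default 1 mm amplitude) roughens the body
and bone surfaces so that hotspot connected components are irregular.
The default grid is 2 mm isotropic — coarser than clinical CT (~1 × 1 × 3
mm) for desk-scale speed; spacing is configurable and structure volumes
converge to their analytic values as the grid refines.

Two placement constraints matter and are enforced by construction:

* the brain sits everywhere at radiological depth ≥ the build-up depth, so
  the coverage quantile is never inside the build-up region;
* the eyes are positioned so their lateral-beam BEV shadows clear the
  dilated brain projection. Eye blocks that shadow brain tissue would zero
  dose there (both beams mirror the same block), push more than 0.1% of
  the brain volume to zero dose, and break coverage normalization — a
  constraint clinical aperture design handles by field shaping, and the
  phantom handles by geometry.

Four presets span the regimes the planner must handle. They differ only in
geometry, chosen from the opposed-lateral dose closed form (below):
`default` (adult-like, strong chord-length spread → hotspots outlast the
subfield budget), `stress` (eccentric, thick bone shell → same, harder),
`mild` (wide head, small brain → a single localized supra-107% ring that
the loop can block to convergence), and `flat` (very wide head, small
central brain, no bone → the normalized dose never reaches 107%; the loop
must add nothing).

## Dose engine

Per-field dose at a voxel factorizes as `T(u, v) · ISq(r) · B(d)`:

* `T` — binary MLC transmission at the voxel's divergent BEV projection
  (similar-triangle magnification through the point source). An optional
  Gaussian penumbra blur exists but defaults to off so aperture-subset
  invariants stay exact.
* `ISq = (SAD/r)²` — inverse-square falloff with distance from the source.
* `B(d)` — depth dose in radiological depth `d` (density line integral
  along the ray): a linear build-up ramp `d/d_max` to `d_max = 1.5 cm`,
  then `exp(−μ(d − d_max))` with `μ = 0.046 cm⁻¹` — water-like 6 MV
  values. The ramp is the simplest model that pushes peak dose off the
  surface into the scalp/bone shell, where whole-brain hotspots live.

Radiological depth is computed on a divergent beam-space raster (2 mm in
(u, v) at the isocenter plane, 2 mm steps along each ray) by trilinear
sampling of the density grid and cumulative summation (midpoint-corrected),
then interpolated back to voxel positions. Depth, inverse-square and
build-up factors depend only on the beam geometry, so they are cached per
geometry: a new subfield costs one transmission lookup and a multiply, and
the weight optimizer never re-raytraces. Plan dose is exactly linear in
the weights.

For equal-weight opposed laterals this model yields the clinical pattern
the loop needs: midline dose `2·e^{−μ(W/2 − d_max)}` for a path of
radiological width `W`, entry-region dose `≈ 1 + e^{−μ(W − 2 d_max)}`
(hotter by a cosh factor plus an inverse-square asymmetry of a few
percent), and short-chord periphery hotter still. No scatter, no
heterogeneity correction beyond radiological depth, no output factors —
the engine is a geometry generator, not a dosimetry claim.

## FIF loop

Hotspots are connected components (26-neighbor by default; 6-neighbor
available) of body voxels at ≥ 107% of Rx, kept if strictly larger than
1 cm³. Detection runs over the whole body — whole-brain hotspots live in
skull and scalp — while the V107% metric is *reported* as a percentage of
the brain volume, matching clinical reporting. The block level each
iteration is `max(h − 3, 107)` % of Rx, where `h` is the current maximum
hotspot percentage: the fixed 3-point decrement trades cold-spot risk
(too large) against iteration count (too small), and the floor at the
target level prevents overshooting into cold spots near convergence.

The block region is the union of **all** body voxels at or above the block
level (blocking per hottest component is a config option). It is projected
into the first main beam's BEV, subtracted from the main aperture, MLC-
conformed, and mirrored for the opposed beam; subfields enter at the
minimum-MU weight floor.

Acceptance and stopping: after optimization and renormalization, the
iteration is accepted only if the hotspot volume (body volume at ≥ 107% of
Rx) did not increase; "size of the hotspot" is read as this volume, with
the peak percentage logged alongside. The loop ends on: target reached
(no qualifying hotspot above 107%), subfield budget (six) exhausted, or
hotspot growth (the pair is reverted). Two degenerate-geometry guards
terminate with distinct reasons: a block with no in-field projection
(no-op) and a subtraction that closes every leaf pair. A separate
iteration cap can be configured; by default the pair budget is the cap.
The loop contains no randomness: identical inputs give identical plans.

### MLC conformance rules

A leaf pair leaves a single open interval per row, which forces a design
choice when a blocked area splits a row:

* Target openings (the whole-brain aperture) use the **over-cover** rule:
  per leaf row, the open interval is the min–max extent of the region, so
  leaves never cut into the target. Excess opening is at most the row-end
  pixels, and the stored BEV raster is the rasterization of the leaf
  intervals, so map and hardware agree exactly.
* Subfield shaping uses the **largest-open-run** rule with an explicit
  avoid map: any leaf-band column containing blocked pixels is treated as
  closed, and the longest remaining contiguous run becomes the open
  interval (ties go to the lower-u run). This is what a planner does when
  a hotspot sits mid-row: close in from one side and give up the smaller
  lobe. A min–max rule would silently re-open interior blocks — on this
  engine the dominant hotspot (the superior scalp "crown") projects to the
  interior of the top leaf rows, and over-cover conformance would make
  every subfield a no-op.

Subfield intervals are subsets of the main-field intervals row by row, by
construction.

## Weight optimization and normalization

Only weights are optimized (forward planning; leaf positions come from the
iso-dose geometry). The cost is a two-sided hinge-quadratic,

    C(w) = α Σ_{v∈body} max(0, D_v(w) − Rx)² + β Σ_{v∈brain} max(0, Rx − D_v(w))²,

α = β = 1, minimized by L-BFGS-B (analytic gradient, gradient tolerance
1e−6, ≤ 200 iterations) from the current weights, with per-field bounds
encoding the 5 MU floor through the linear weight→MU map (default 100 MU
per unit weight per fraction; an explicit stand-in for machine MU
calculation). The overdose term runs over the body rather than the target:
hotspots sit outside the brain, and a target-scoped overdose term is
provably flat along the main-to-subfield weight-exchange direction, which
would stall the loop. A failed or worsening solve returns the starting
weights — the optimizer never degrades a plan.

Coverage is enforced by normalization, not by the solver: all weights are
scaled by one exact scalar so the 99.9% coverage quantile of brain dose
equals Rx (renormalization to e.g. 99.5% of Rx is the `dose_level`
setting). The scalar comes from the voxel-dose quantile directly, which
agrees with the 0.01 Gy-binned DVH inverse within one bin; normalization
is idempotent at that tolerance. Because rescaling can push a floor-level
field below its MU minimum, normalization and floor-clamping run as a
short fixed-point loop (≤ 8 passes; floor fields carry negligible dose, so
it converges immediately in practice).

## Evaluation

Cumulative DVHs use 0.01 Gy bins — fine enough for the 0.2 Gy-scale
coverage comparisons the report makes — with linear interpolation for
Dx/Vx lookups. The report carries brain D99/D95/D1, mean eye dose, maximum
lens dose (single hottest voxel by default; a dose-to-small-volume
alternative, e.g. D0.03cc, is a parameter), V107% in cm³ and as % of brain
volume, the maximum hotspot percentage (100 · max body dose / Rx) and the
maximum plan dose in Gy as separate fields. Missing structures are listed
and the rest still computed.

## What the synthetic results show — and what they cannot

Passing tests demonstrate the *algorithmic* contracts on this substrate:
normalization exactness, the three-way stopping rule, the 3%-decrement
arithmetic, hotspot-volume monotonicity under the accept rule, MU floors,
parity and aperture-subset geometry, and convergence to ≤ 107% where the
geometry permits it. The phantoms reproduce the qualitative clinical
picture (initial V107% of roughly two-thirds of the brain volume;
peripheral skull/scalp hotspots) but none of the patient-cohort numbers:
real heads, real scatter physics and TPS dose engines will move every
dose figure. In particular the default phantom's initial 130% peak is
harsher than typical clinical opposed-lateral plans, so six subfields
reduce rather than resolve it; that regime is intentional, to exercise
the budget-exhaustion path.

Known limitations: no wedge subfields; no landmark-based aperture design
(the whole-brain aperture is a dilated brain projection minus eye/lens
shadows, margin 7 mm); "point" normalization is exposed in configuration
but not implemented; single-interval leaf pairs cannot represent
annulus-shaped subfields (handled by the largest-open-run rule); the dose
engine ignores scatter, leaf transmission and penumbra by default; DICOM
support is a minimal RT Dose export only. Problem sizes default to 2 mm
grids (≈ 0.7–1.7 M voxels per phantom), where a full pipeline run takes a
few seconds.
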