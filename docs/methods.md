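# Methods

## Morphometry database and weighted aggregation

The packaged CSVs (`src/aortagen/data/table*.csv`) transcribe a literature
survey of healthy adult aortic morphometry: one row per study sub-cohort
with study id, imaging modality (CT/CTA/MRI/CMR/echo/DSA/angiography/
cadaver/review), age note, sub-cohort label (male/female/all), cohort size
n, symbol, value and unit.  Missing cells are kept as empty values so the
database mirrors its sources.

The only statistic used is the cohort-size-weighted mean Σnᵢvᵢ/Σnᵢ.
Counting rules: male/female sub-cohorts are independent entries; a study
contributes to a column only if it reports it, and its subjects then count
toward that column's cumulative N.  This rule reproduces the published
cumulative cohort of 8,071 subjects for the ascending diameter exactly.
No heterogeneity analysis or confidence intervals are attempted — the
sources report means at mixed precision without consistent dispersion
data, so anything beyond the weighted mean would be false precision.

A few published summary cells cannot be reproduced from the published
per-study rows under any defensible counting rule (examples: the Bovine
trunk diameter summary, one branch-spacing cumulative N off by one).  The
transcription metadata (`aggregates.csv`) flags these `mean_verified` /
`n_verified` false; tests and the acceptance script assert only verified
cells.  Both the directly aggregated value and the published summary value
are retained — the summary parameter set (`table10_defaults.yaml`) is
what the models are built from, the per-study tables are what aggregation
is verified against.

## Centerline model

Anatomical frame: +x left, +y anterior, +z superior; the sinotubular
junction (STJ) is the arc-length origin.  The printed dimensions constrain
the curve but do not define one, so the package commits to the simplest
curve class meeting every constraint with tangent continuity:

* ascending segment: straight, length L, directed superiorly;
* arch: in its own vertical plane, a semi-ellipse with horizontal span W
  and height H — the unique smooth conic with vertical limbs at both ends
  (C¹ junctions with ascending and descending segments) that meets the
  height/width extents exactly;
* transverse bend: a lateral offset profile η(ξ) = √(R²−(ξ−W/2)²) − √(R²−(W/2)²)
  added perpendicular to the arch plane, which makes the axial projection
  of the arch *exactly* a circular arc of radius R with chord W.  R < W/2
  cannot close the arch and raises an infeasibility error;
* descending limb: a cubic Bézier blend (length H/2, C¹) from vertical
  into the straight direction d(β₁,β₂), followed by a straight segment.

Angle conventions (the sources define β₁–β₃ only pictorially): β₁ is the
polar tilt of the final descending direction from vertical; β₂ rotates its
horizontal component from posterior toward the left; β₃ rotates the arch
travel direction in the transverse plane from posterior toward the left.
These are mutually independent and each is recoverable from geometry
alone, which is what the measurement suite does.  Arch height/width are
measured in the arch's own (β₃-rotated parasagittal) plane, so recovery is
exact rather than biased by cos β₃.

Branch stations are centerline arc lengths: BA at s=a, LCA at a+d1, LSA at
a+d1+d2 (Type I), trunk at a and LSA at a+d3 (Type II); a station past the
arch end raises an error naming the branch.  Distances a, d1, d2, d3 are
interpreted as arc lengths (well defined on any curve); the sources do not
state whether they were measured along the vessel or as chords.

The radius law r(s) is a monotone piecewise-cubic (PCHIP) interpolant
through D1/2 (STJ and arch start), D2/2 (arch apex) and D3/2
(mid-descending and outlet): between knots the radius never overshoots the
knot interval, so prescribed diameters are honored exactly at their
stations.

Sampling: the user chooses a resolution in rings/cm (default 6); sample
stations are snapped onto landmarks and branch stations so every station
coincides with a lattice ring, making recovered spacings limited by
polyline arc-length error (~0.05%) instead of half a ring spacing.

Frames: cross-sections are oriented by rotation-minimizing frames
(double-reflection propagation), not Frenet frames, which flip at
inflections of 3D curves.  Propagation runs once on a fixed 4096-step
internal grid and is interpolated to the output sampling, so frames are
independent of the requested resolution.

## Mesh construction

The surface is a structured quad lattice (rings × K circumferential
samples, default K=64), triangulated with consistent outward winding.
Junctions are built by *stitching*, not booleans: a rectangular patch of
lattice cells around the branch axis' wall-pierce point (offset r·cotα
downstream of the station for oblique takeoffs) is removed, and a
transition collar morphs the patch boundary onto a circular tube while
redistributing vertex angles uniformly, so the tube's far rings are
regular polygons on the exact prescribed circle.  With the boundary loop
oriented counter-clockwise about the outward branch axis, the collar's
winding is consistent with the surrounding wall by construction.  The
result is watertight, edge-manifold and genus 0 without any boolean
engine, and fully deterministic (identical parameters give byte-identical
STL).  The patch is cut at 0.75 of the branch footprint so adjacent
branches at minimum printed spacings do not collide; overlapping patches
raise an infeasibility error rather than producing a broken mesh.

The aortic root is a parametric stand-in for the reference root model the
original construction borrowed (which is not redistributable): cross
sections below the STJ carry three sinus-of-Valsalva lobes
(½(1+cos 3θ) azimuthal profile, sin² axial bump) whose maximal diameter is
`sinus_bulge_ratio` (default 1.3) times the STJ diameter over a sinus
height of 2.2 cm, blending to circles at the annulus and STJ.  Coronary
stubs (diameters C1, C2, in mm) leave radially from the anterior and
left-posterior sinuses at the bulge maximum.  A bulge ratio of 1 gives the
documented degenerate cylindrical root; below 1 is rejected.

The LVAD outflow cannula (default 16 mm diameter) is stitched into the
mid-ascending aorta at 45° elevation, anterior azimuth — the sources place
it only as "clinically common", so the location and angle are explicit,
overridable spec fields.  The inlet cap sits exactly `inlet_extension`
diameters (default 15, i.e. 240 mm) from the anastomosis point along the
cannula axis, giving the fully developed inflow length used in flow
studies; zero extension leaves a one-diameter collar.  After grafting the
cannula cap is relabeled `inlet` and the root end `root`.

Shelling offsets every vertex along its outward vertex normal by the wall
thickness (default print shell 1.0 mm; 0.6 mm for the optically thin PIV
variant), removes the selected end caps, and welds inner and outer
surfaces with boundary annuli into a closed solid wall.  Thickness
fidelity is verified by inward ray casting at random surface points
(mean within ±10% passes); vertex-normal offsetting is exact on smooth
regions and slightly under-thick only in concave junction corners.

`assemble` is the generic union for arbitrary watertight parts: parts are
sampled as signed-distance fields on a voxel grid (sign by vertical-ray
parity, magnitude by exact point-to-triangle distance against KD-tree
candidates), combined by (smooth-)minimum — a polynomial smooth-min
confined to ~2× the blend radius around intersection curves — and
re-surfaced with marching cubes.  Its accuracy is voxel-limited; the main
pipeline never needs it because stitching joins parts exactly.

Units: geometry is built in cm; mesh files are written in mm (the
3D-printing and CFD convention).  STL (binary/ASCII), OBJ and PLY are
supported, with boundary labels and lattice structure in a JSON sidecar
(mesh formats cannot carry them).  PLY round-trips the full structure;
STL is an unindexed float32 triangle soup, so reloading merges vertices,
keeps ~1 µm coordinate precision only in the float32 sense, and drops the
lattice structure (face-level labels survive).

## Measurement (inverse QA)

Measurements use mesh geometry plus stored lattice *connectivity* (which
vertices form each ring) — never stored coordinates — so a rescaled mesh
fails its length rows while passing its angle rows:

* diameters: mean vertex distance to the ring centroid (exact for the
  circular rings the generator produces; an inscribed-polygon area would
  bias low at low vertex counts).  The standalone `slice_diameter`
  operator instead cuts any mesh with a plane and returns the
  equivalent-area diameter 2√(A/π) of the single closed section loop,
  erroring on empty/open/multi-passage cuts;
* centerline: ring centroids; stations as polyline arc length from the
  STJ ring; H/W from the arch-start/apex/end centroids; R by algebraic
  circle fit of the transverse arch projection; β from the terminal
  direction and the arch end azimuth;
* branch angles: principal axis of the cylindrical branch-ring centroids
  (the junction collar is excluded) against the local aorta tangent from a
  local polynomial fit in arc length — the fit window is clipped at the
  arch start/end junctions where the curve is only C¹, since a window
  straddling the curvature jump biases the derivative.

Default tolerances are 2% for lengths and 1° for angles: comfortably
above the discretization floor at default resolution (≤0.2% / ≤0.4°) and
below dimensional differences of clinical interest.  The validity block
reports watertightness, winding consistency, Euler characteristic/genus
(over face-referenced vertices; lattice vertices inside cut patches stay
in the array to keep ring indexing intact), minimum triangle angle, and a
self-intersection count from edge-vs-triangle tests over KD-tree candidate
pairs (coplanar-overlap contacts without edge crossings are undetectable,
which cannot occur on these smooth surfaces).

## Flow-condition helpers

Blood is Newtonian with ρ=1060 kg/m³ and μ=0.004 Pa·s.  For flow Q
through diameter D: U = Q/(πD²/4) and Re = 4ρQ/(πμD).  The two LVAD
support settings, 5 and 9 L/min through the 16 mm cannula, give Re ≈ 1757
and 3163 and a half-bulk-velocity jet threshold of ≈0.2 m/s.  No CFD or
turbulence modeling is in scope; the helpers pin down the inflow
conditions a downstream solver or rig should impose.

## Verification scope and limitations

Tests verify parameter *recovery*: that generated geometry returns its
inputs under independent measurement, that measurement operators agree
with closed forms on analytic primitives (cylinder slices, torus areas)
with error decreasing under refinement, and that aggregation matches a
brute-force oracle to 1e-12.  The randomized round-trip draws parameter
sets within ±20% of the defaults; draws violating the parameter set's own
invariants (D1>D2) or geometric feasibility (branch stations beyond the
shrunken arch, overlapping branch footprints) are redrawn deterministically
— the property quantifies recovery on feasible anatomies, which is the
generator's contract.  Geometry checks in the test suite run at 4 rings/cm
and K=48 for speed; the two default models are exercised at the default
6 rings/cm, K=64.

What passing does **not** show: fidelity to any individual anatomy (the
models are population averages; real aortas are non-circular, tapered
non-monotonically, and have non-planar branch takeoffs), hemodynamic
realism (rigid walls, no valve — the valve is deliberately excluded as a
dynamic component), or the descending length below the mid-descending
station, which is a free choice (default H+W ≈ 12 cm) scaled with the
model.  The root is a parametric stand-in, not a replica of the reference
root geometry.
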