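# Methods

This note documents the model, the numerical choices and the limits of what
the test suite demonstrates. All lengths are in Å.

## Model

An atom is a sphere with its van der Waals radius (packaged Bondi-style
table; the radius set is exposed as data, `cavipath/data/vdw_radii.csv`, and
is a user-replaceable choice, not a claim of universality). The signed
distance of a point to atom *i* is `d_i(p) = ‖p − p_i‖ − r_i`. The additively
weighted Voronoi diagram of the spheres partitions space by `min_i d_i`; its
vertex–edge graph contains all curves along which clearance to the van der
Waals surface is locally maximal (maxima, index-2 saddles and their
separatrices). Only this graph is computed — facets and full regions never
are.

A **static molecular path** for a probe of radius `r_p` is the part of this
graph that (a) lies inside the molecular domain and (b) keeps clearance
≥ `r_p`. Its connected components are **path components**, and each
component's **cavity** is the union of the empty tangent spheres at its
vertices and along its edges. **Dynamic cavities** are chains of per-frame
cavities linked by sufficient geometric overlap across consecutive frames.

## Degeneracy handling

Exact cosphericality (≥ 5 atoms tangent to one empty sphere) breaks the
one-vertex-per-4-atoms assumption. Every frame is therefore perturbed once,
before any computation, by independent uniform displacement vectors of length
≤ ε = 1e-6 Å — small enough to be irrelevant for structural analysis (tests
assert cavity volumes move by ≪ 0.1 %) and large enough to separate
degenerate vertices in double precision. Each frame's perturbation seed is
derived from `(seed, time_index)`, so frames are independently reproducible.
If coincident vertices with different generator quadruples survive within
1e-12 Å, a `DegenerateConfigurationError` asks for a (re-)perturbation.

## Voronoi graph computation

**Vertices.** For a candidate 4-subset the tangency system
`‖v − p_i‖ = c + r_i` reduces (by subtracting one equation) to a linear
system `v = v0 + c·v1` plus one quadratic in `c`: up to two real solutions,
solved in closed form and batched over all candidates with dense linear
algebra. Solutions are kept iff the tangency residual is < 1e-8 (this kills
the spurious sign branch), the position lies inside the frame bounding box
expanded by `bounding_margin` (default 5), and the empty-sphere property
holds against all atoms with slack 1e-9 — deliberately far below ε, since a
slack comparable to the perturbation re-admits the degenerate near-ties the
perturbation just resolved.

Candidates are all `C(n,4)` subsets for n ≤ 30, and the Delaunay tetrahedra
of the centers above that. For equal radii (all synthetic fixtures) the
weighted diagram is the point Voronoi diagram, so Delaunay candidates are
exact; for strongly mixed radii at large n this is a documented heuristic —
the brute-force route remains available via `exact_enumeration_limit`.
Spheres entirely contained in another are dropped up front (their region is
empty) and noted in the log.

**Edges.** From each vertex, along each generator triple, the equidistance
locus is traced by predictor–corrector marching: the tangent is the cross
product of the two constraint gradients, the corrector is a Gauss–Newton
projection onto `d_1 = d_2 = d_3` (residual < 1e-10), and the step adapts to
keep the tangent turn < 25° (chord sag ≈ 0.02 at the 0.35 step cap). The
initial direction is the one along which the fourth generator's distance
grows. A trace ends by snapping onto another vertex of the same triple
(bounded edge), by clipping at the expanded box (unbounded edge), or — as a
guarded fallback — where the empty-sphere property fails without a known
vertex nearby. Each polyline then gets its interior **clearance minima**
inserted explicitly (sign change of the clearance derivative, located by
golden-section search with curve projection): these minima are the index-2
saddles, i.e. the constrictions that decide whether a probe passes, and they
routinely fall between marching steps.

## Filtering

**Ambient occlusion.** The domain of the molecule is delimited
operationally: from each vertex we cast a deterministic low-discrepancy ray
set (Fibonacci directions under a seeded random rotation, default 256 rays)
and measure the fraction that escape without hitting an atom sphere. Vertices
receiving more light than the threshold (default 0.15) are removed with
their incident edges. Occlusion is evaluated at vertices only; an edge
survives iff its endpoint vertices do, and box-clipped unbounded edges are
removed whenever occlusion is active since their free end is outside by
construction. Vertices with clearance ≤ 0 are buried and receive no light by
definition (ray casting from inside an atom is undefined). Whether a 15 %
escaping-ray fraction equals any other occlusion normalisation is not
claimed; the threshold is a parameter.

**Probe pass.** Vertices with clearance < `r_p` are removed; edge polylines
are cut into maximal runs of samples with clearance ≥ `r_p`. Each truncated
run end becomes a terminal *pseudo-vertex* with clearance exactly `r_p`,
located on the true edge curve by bisection with Gauss–Newton projection
(a linearly interpolated crossing can sit slightly off the curve, where its
true clearance is below `r_p`, which would poison the sphere placement
below). Pseudo-vertices are flagged and excluded from occlusion testing.

Components are ordered by total clearance-weighted arc length (ties by
sorted vertex ids), making cavity ids reproducible.

## Cavity construction

Cavity spheres are the vertex tangent spheres plus edge spheres sampled so
that consecutive spheres satisfy the probe-continuity criterion: the largest
circle inside their intersection has radius ≥ `r_p`. Between polyline
samples, midpoints are inserted recursively (≤ 24 levels); each inserted
point is projected onto the edge curve and its radius recomputed as the
exact largest empty-sphere radius at that point (min over atoms via a
k-nearest query, exact for uniform radii), keeping the no-atom-intersection
invariant exact rather than trusting interpolation. Where the projection
overshoots past a parent sample (sharp bends near vertices) nearby chord
parameters are tried instead. The criterion is genuinely unattainable only
if the clearance minimum equals `r_p` to ≈ 1e-14 — measure-zero after
perturbation — and then raises `EdgeSamplingError` rather than emitting an
invalid chain.

**Inscribed intersection circle.** For spheres at center distance `d`: no
circle if `d ≥ r1 + r2`; `min(r1, r2)` if `d² ≤ |r1² − r2²|` (the smaller
sphere's great circle fits inside the larger sphere — a wider regime than
full containment, and the value the direct constrained maximisation over
tilted disks confirms); otherwise the lens rim circle
`sqrt(r1² − x²)`, `x = (d² + r1² − r2²)/(2d)`. The containment-band value is
what makes the placement criterion attainable near truncation points, where
sphere radii approach `r_p`.

## Volumetrics

Exact union-of-spheres volumes are avoided deliberately (complex and
numerically brittle); instead a cube grid of side `a` (default 0.2) spans
the cavity's bounding box, anchored at its min corner with cube centers at
`origin + (i + ½)a`, and counts cubes whose center is *strictly* inside at
least one sphere (ties are measure-zero after perturbation). Intersection
volumes use one shared grid over the intersection of the two bounding boxes
— hence exactly symmetric in its arguments — and ignore spheres that do not
reach the reduced box; this equals the full-box count by construction, since
a cube center inside spheres of both cavities necessarily lies in both
boxes. Counts are integers, so any parallel accumulation order gives
bit-identical results. Grid error on a unit sphere falls below 1 % at
`a = 0.05`, and Monte-Carlo cross-checks agree within 3σ on random unions.
Water capacity uses the common ≈ 30 Å³-per-molecule approximation,
floor-rounded.

## Time tracing

Two cavities of consecutive frames correspond when the maximum over sphere
pairs of the inscribed intersection-circle radius is **strictly greater**
than `r_ic` (default `r_ic = r_p = 1.4`, since the same probe that defines
the paths should be able to move through the overlap). The sphere-pair scan
is KD-tree pruned but exactly equals the all-pairs maximum. Each
correspondence edge stores both the circle radius (the decision) and the
grid intersection volume (the matching weight), so matching never recomputes
volumes.

Identities: first-frame cavities are numbered in cavity-id order; per
transition, the bipartite edges are sorted by intersection volume
descending — ties broken by ascending `(identity_t, cavity_id_{t+1})`, a
deterministic completion of an otherwise ambiguous heuristic — and matched
greedily, skipping edges with an already-matched endpoint. Matched nodes
inherit; every unmatched node gets a fresh, never-reused number.

Dead-end removal deletes nodes with no surviving continuation (while a later
frame exists) and propagates backwards until a node keeps another forward
edge; final-frame survivors are kept, since no following frame exists to
continue into. Forbid-splits keeps only matched continuations per
transition; unmatched nodes that have incoming correspondence edges (split
remnants) are dropped, while nodes with no incoming edges are genuinely new
cavities and start fresh chains; identities are reassigned on the pruned
graph so each identity is a simple path. Dynamic-path extraction runs a
forward-in-time depth-first search per selection leg, trying larger
intersection volumes first (the preference rule is this package's choice).

## Timelines and residence probability

The split/merge layout is one row per identity (plain top-to-bottom
ordering), with per-frame volume as the drawn thickness and explicit event
rows; events are recorded at the later frame of a transition. Evolution
profiles report, per identity and frame, the projection interval
`[min(c·axis − r), max(c·axis + r)]` over the cavity spheres. Residence
grids share the `(i + ½)a` cube convention anchored at the union bounding
box over the frame range, so a single-frame residence grid equals the
occupancy grid exactly and every value is `k/T`. Rendering (isosurfaces,
maximum-intensity projection, skin surfaces) is delegated to external
viewers through the OpenDX export; a helper reports the cube count above a
threshold ("stable core" size).

## Synthetic fixtures

Fixtures are deterministic and their ground truth comes from construction,
never from the code under test. They use a single atom radius (default
1.8 Å, matching the packaged sulfur radius so a PDB round trip reproduces
radii exactly) so closed forms stay available; mixed radii are exercised by
the random-sphere oracle tests instead.

* `tetra_cage(edge, r)`: one interior vertex at the centroid, clearance
  `edge·√(3/8) − r`.
* `shell_pocket(R, r, n, mouth)`: Fibonacci-lattice shell, leak-free iff the
  nearest-neighbor spacing is < 2r (enforced); mouth 0° is the closed cage
  whose center receives zero ambient light; interior cavity volume
  ≈ (4/3)π(R − r)³.
* `channel_tube(L, ρ_min)`: staggered atom rings along z with a central
  bottleneck ring; open ends stand in for the two sides of a membrane
  channel. Bottleneck 2.0 passes a 1.4 probe (one spanning component);
  1.0 blocks it.
* `splitting_dumbbell(schedule)`: two spherical bulbs joined by a cylindrical
  neck whose free radius follows a per-frame schedule crossing the probe
  radius exactly once; ring atom counts come from the widest schedule value
  so all frames share one atom list. The default schedule (2.0→1.7 over
  frames 0–4, then 1.2→0.7) splits at frame 5; its reverse merges at
  frame 5. The neck is cylindrical, not conical: a cone produces secondary
  constrictions near the bulbs and hence spurious transient pockets.

What the fixtures do **not** emulate: realistic protein packing, mixed
radii, thermal noise on atom positions, solvent, or force-field dynamics.
Passing tests demonstrate geometric and algorithmic correctness of the
pipeline, not biological conclusions about any particular protein.

## Problem sizes and defaults

Defaults: `r_p = 1.4`, occlusion threshold 0.15 with 256 rays,
`a = 0.2`, `r_ic = r_p`, ε = 1e-6, bounding margin 5. The shipped analyses
use fixtures of 80–120 atoms and trajectories of 3–10 frames — sizes at
which the exhaustive geometric cross-checks (brute-force enumeration,
Monte-Carlo, constrained maximisation) stay practical; the pipeline itself
scales to larger frames through the Delaunay candidate route and KD-tree
pruning.

## Known limitations

* Delaunay-based vertex candidates are exact only for equal radii; strongly
  heterogeneous radii at n > 30 may miss vertices whose generator set is not
  a Delaunay tetrahedron (raise `exact_enumeration_limit` to force
  enumeration).
* Edge tracing is numerical; a conic branch carrying no vertex (an isolated
  closed-loop edge) is not discovered.
* The occlusion filter is an operational definition of "outside the
  molecule"; its threshold is not comparable across differently normalised
  occlusion estimates.
* Volumes are grid approximations with O(a) boundary error.
* `read_multimodel_pdb` requires identical atom ordering across MODELs; no
  topology or bond perception is done, and binary MD formats are not read.
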