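# Methods

## Problem and model

A segmented object is given as an ordered stack of parallel slices at
strictly increasing z, each slice holding one or more closed polygonal
contours (millimetres throughout; slice spacings of 1–5 mm are the typical
CT regime the fixtures emulate). The reconstruction interpolates a triangle
surface between each pair of consecutive contours and closes the ends, so
that the output is a watertight, outward-oriented mesh. The method
deliberately preserves the original contour points and introduces no new
ones; the single exception is keyhole handling, which *removes* points from
inside narrow channels.

Contours are implicitly closed rings (first point not repeated), wound
counter-clockwise viewed from +z, 0-based indexed. These conventions are
this package's own: with n points equal to n segments, the tiling index
arithmetic has no duplicate-point corner cases, and fixed CCW winding plus
increasing z makes every face winding deducible locally. Input winding is
normalized on load rather than rejected.

The correspondence problem — deciding which contours across slices belong
to the same object — is assumed solved by the stack ordering and is not
addressed. Complex branching (saddle topology, annular sections, coronal
cuts producing disconnected regions) is likewise out of scope.

## Tiling as a shortest monotone path

For rings with n and m points, a tiling is a monotone lattice path of
n + m moves from span P(0,0) to P(n,m); move "advance i" lays the tile
(L[i], L[i+1], U[j]) and "advance j" the tile (U[j], U[j+1], L[i]), with
indices modulo ring length. Tile areas come from the cross product,
|BA × BC| / 2; collinear (zero-area) tiles are legal with cost 0. Because
moves only ever increase i or j, a row-by-row dynamic program that keeps,
at every span, only the cheaper incoming path is exact — no general
shortest-path machinery is needed — and runs in O(nm) time and memory.
Cost ties between the two incoming moves prefer "advance i", making the
backtracked path deterministic.

The span graph is toroidal (both rings are cyclic). The default cuts it
open at the *closest point pair* between the two rings (ties resolved to
the lowest (i, j)), then runs one DP sweep. An optional exhaustive mode
re-runs the sweep from every upper-ring start offset j0 ∈ [0, m) and keeps
the cheapest result; since any tiling cycle passes at least one span with
lower index 0, this search attains the true minimum-cost cycle. It costs a
factor m more and the closest-pair start is almost always on an optimal
cycle, so the single sweep is the default.

## Normalization

Minimizing raw area fails a classic stress case: two congruent circles
whose centers are offset one diameter collapse into a double cone pinched
along a line rather than the obvious skewed cylinder. To make the metric
judge *shape* correspondence, each contour may be normalized before costs
are measured: translate so the vertex centroid (arithmetic mean of ring
points — simpler and order-robust for roughly uniformly sampled rings;
an area centroid would also be defensible) lands on (0, 0), then scale
x by the bounding-rectangle width and y by its height,

    x' = (x − cx) / width,   y' = (y − cy) / height,

so the window becomes the unit square. z is left untouched, so the cost
still sees inter-slice distance. The exact scale constant (unit square
versus unit half-width) is a free choice; any fixed window-proportional
scale yields the same optimal correspondences for congruent sections.
Normalization is a cost-metric transform only — the start span is found in
the same normalized coordinates, and emitted tiles always carry original
coordinates. It defaults to on; `--no-normalize` turns it off, which on
near-aligned stacks gives indistinguishable results.

A note on determinism at exact ties: for perfectly congruent aligned rings
every lateral quad's two diagonal splits tie exactly, and which split the
DP picks depends on sub-ulp rounding of the normalized coordinates. The
*matching* (which lower point pairs with which upper point) is stable; the
interleaving of tied moves is not guaranteed identical between, say, an
aligned and a translated copy of the same stack. Tests therefore assert the
matching, not the tie ordering. Any single stack reconstructs bitwise
identically run after run.

## Branching

When one slice holds more contours than its neighbour (m ≠ n, both > 0),
the richer slice's contours are merged into composite rings until counts
match: repeatedly take the two contours with the smallest cross point
distance and bridge them with one edge between their globally nearest
points p and q (lowest-index pair on ties). The composite traverses ring 1
to p, jumps to q, walks all of ring 2 back to q, jumps back to p, and
finishes ring 1 — n1 + n2 + 2 points with p and q each visited twice, CCW
winding preserved (the bridge is traversed both ways and contributes zero
signed area). Merging requires disjoint contours; overlap is an error.

The pipeline sweeps slice pairs in z order, so a merge on one slice
propagates: a stack whose single contour splits into two collapses, pair
by pair, to one composite ring per slice, and an equal-count pair is never
touched (unbranched stacks pass through unchanged). A stack that holds
several contours per slice on *every* slice has no branching event to
resolve and is rejected at tiling — that is the correspondence problem,
out of scope. The doubled bridge points would make degenerate (zero-area)
faces in the final mesh; assembly drops those two faces, which is why the
composite-ring fixtures still close up watertight.

## Keyholes

Two ring points are in conflict when their distance is below the threshold
and they are not adjacent, where "adjacent" means within 2 index steps
along the ring (1 step would flag nothing useful; large windows would miss
short channels; 2 avoids flagging neighbouring edges on dense contours).
Conflicts are resolved lowest-(i, j) first: the shorter of the two arcs
strictly between i and j (by point count, ties take the forward arc) is
the channel interior; its points are removed and i joined directly to j.
The scan repeats until no conflict remains, which makes the operation
idempotent and guarantees the postcondition that every surviving
non-adjacent pair is at least the threshold apart. Each removal deletes at
least two points, so termination is immediate; with the 2-step adjacency
window a ring can never shrink below 4 points this way (the <3-point guard
is defensive). The default threshold is 1.5× the contour's median edge
length — a relative default that adapts to contour density and flags
nothing on convex, uniformly sampled sections.

## Sealing and assembly

End contours are capped by triangulating the polygon interior using only
its own vertices: constrained Delaunay triangulation honoring the ring
edges (plain Delaunay of the vertex set would spill outside concave
sections), with an O(n²) ear-clipping fallback should the constrained
backend decline an input. Both produce exactly n − 2 triangles covering
the polygon with no overlap; caps are wound CW (bottom) or CCW (top)
viewed from +z so normals point away from the interior. Caps with interior
holes are not supported.

Assembly merges all tilings and caps into one indexed mesh, deduplicating
vertices by *exact* coordinate equality — contour points are passed
through untouched, never recomputed, so bitwise matching is safe and
avoids epsilon-welding pitfalls. The watertightness report counts boundary
edges (1 incident face), non-manifold edges (>2), the Euler characteristic
V − E + F, and checks that every interior edge is traversed in opposite
directions by its two faces. Writers emit binary STL, ascii PLY and ascii
OBJ; PLY/OBJ print shortest round-tripping decimal reprs so indexed
coordinates survive a write/read cycle exactly (STL is float32 by format).

## Synthetic fixtures

The generator produces the geometries the pipeline is exercised and
accepted on: circular cylinders (uniform angular sampling starting at
angle 0, so expected correspondences are predictable), cones tapering to
30% radius, skewed cylinders whose centers shift one diameter per slice
(the normalization stress case), a Y-branch whose single section splits
into two, a C-shaped section with a 0.2 mm channel (detected at the
documented 0.5 mm threshold), and seeded random convex sections sampled on
the convex curve r(θ) = R(1 + 0.3 sin(θ + φ)), whose curvature stays
positive so every inscribed polygon is convex. Defaults are radius 10 mm,
32 points per contour, 5 slices at 2 mm spacing, inside the 1–5 mm CT
range. All randomness flows through an explicit seed; the same spec and
seed give bitwise-identical stacks.

What the fixtures do *not* emulate: segmentation noise, point-count
variation along the stack, strongly concave or rapidly changing bone
cross-sections, and multi-object slices. Passing tests therefore
demonstrate correctness of the algorithmic core (optimality of the DP,
topological closure, the stated postconditions) — not reconstruction
fidelity on real anatomies.

## Verification choices and problem sizes

The DP is checked against exhaustive enumeration of all C(n+m, n) monotone
paths on 100+ random pairs with n, m ≤ 7 — small enough for enumeration
(≤ 3432 paths) yet large enough to exercise every move pattern; the
enumeration oracle computes areas by Heron's formula to stay independent
of the implementation. Closed forms anchor absolute areas (prism lateral
surface, inscribed n-gon prisms at n up to 128) and volumes
(divergence-theorem signed volume of a square prism, tolerance 1e−9
relative). Watertightness is asserted over all unbranched fixture kinds at
3 and 10 slices and 1 and 5 mm spacings, and cross-checked against an
independent mesh library in the unit suite. Acceptance-style runs complete
in well under a minute on one core.

## Known limitations

* Branching handles count changes only; saddle-correct topology, holes and
  coronal-cut fragment patterns are not modelled.
* Multi-contour-per-slice stacks with no count change anywhere are
  rejected (correspondence unsolved by construction).
* The closest-pair start span is a heuristic cut of the toroidal graph;
  the exhaustive mode exists when the true cycle optimum matters.
* Tie interleaving on exactly congruent sections is floating-point
  sensitive (see Normalization); matchings and meshes per input are still
  deterministic.
* Rapid shape changes between adjacent slices can funnel many triangles
  into a single point of the smaller contour; the mesh remains valid but
  locally low quality.
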