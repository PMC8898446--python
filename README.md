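# slicemesh

Watertight 3D triangle meshes from stacks of parallel closed 2D contours.

Segmented anatomical structures — femur and tibia cross-sections from CT,
for example — are typically stored slice by slice as closed polygonal
contours on evenly spaced parallel planes. `slicemesh` interpolates such an
ordered contour stack into a single watertight surface mesh, the kind of
model needed by computer-assisted surgical navigation and preoperative
planning. No imaging data is required to use or test the package: a
fixtures module generates synthetic stacks (cylinders, cones, offset
cylinders, Y-branches, keyhole shapes) that emulate segmented bone
cross-sections.

## The method

The band of surface between two consecutive contours is built from
elementary triangular *tiles*, each using one contour segment (two
consecutive points of one ring) plus a single point of the adjacent ring.
An edge pairing lower point *i* with upper point *j* is a *span* P(i, j);
from P(i, j) a tiling may only advance to P(i+1, j) or P(i, j+1), laying
down one tile per move, so a complete tiling of rings with *n* and *m*
points is a monotone path of n + m moves from the start span P(0, 0) to
P(n, m). Each move is weighted by the area of its tile,

    BA = A − B,  BC = C − B,  N = BA × BC,  Area = (N·N)^1/2 / 2,

and the minimum-total-area path — found by an exact O(nm) dynamic program
that keeps only the cheaper incoming path at every span — is the tiling
used. Because both rings are cyclic the underlying graph is toroidal; it is
cut open at the closest point pair between the two rings (an exhaustive
mode re-runs the sweep from every start offset).

Around this core the pipeline runs, in order:

1. **Branching** — when adjacent slices hold different numbers of contours
   (m ≠ n, n > 0), the richer side's contours are bridged into one
   composite ring by a single edge between their nearest points.
2. **Keyhole removal** — non-adjacent ring points closer than a threshold
   destabilize tiling; the points inside the narrow channel are removed and
   the ring re-closed.
3. **Normalization** (optional, on by default) — each contour is translated
   so its vertex centroid sits at (0, 0) and scaled so its bounding
   rectangle becomes the unit square before areas are measured, so the
   metric judges shape correspondence rather than position and size.
   Without it, two identical circles offset one diameter apart tile into a
   degenerate double cone instead of the obvious skewed cylinder. Output
   geometry always keeps the original coordinates.
4. **Tiling** of every consecutive slice pair as above.
5. **Sealing** — the first and last contours are closed with planar caps
   (constrained Delaunay triangulation of the polygon interior, ear
   clipping as fallback), wound so all normals point outward.

For an unbranched sealed stack the result is a closed, consistently
oriented genus-0 surface: every edge borders exactly two faces and
V − E + F = 2.

## Worked example

```sh
$ slicemesh fixture cylinder femur_like.json --n-slices 5 --spacing 2 --radius 10
wrote cylinder stack to femur_like.json
$ slicemesh reconstruct femur_like.json femur_like.stl --report report.json
femur_like.stl: 160 vertices, 316 faces, watertight (boundary=0, non-manifold=0, Euler=2)
```

The fixture is a 5-slice stack of 32-point circles of radius 10 mm spaced
2 mm apart. The reconstruction has 5 × 32 = 160 vertices; each of the 4
slice pairs contributes 32 + 32 = 64 lateral triangles and each cap
triangulates a 32-gon into 30 triangles, giving 4·64 + 2·30 = 316 faces.
`watertight` with 0 boundary edges, 0 non-manifold edges and Euler
characteristic V − E + F = 2 confirms a closed genus-0 surface; the report
JSON also lists any keyhole conflicts that were repaired. The same can be
done from Python:

```python
from slicemesh import FixtureSpec, make_fixture, reconstruct, signed_volume

stack = make_fixture(FixtureSpec("cylinder", n_slices=5, spacing=2.0))
result = reconstruct(stack)               # normalize=True, seal=True
print(signed_volume(result.mesh))         # ≈ π r² h for a dense ring
```

The canonical on-disk stack format is plain JSON:
`{"slices": [{"z": 0.0, "contours": [[[x, y], ...], ...]}, ...]}` with
coordinates in millimetres.

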