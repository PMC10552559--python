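# Multi-block channel geometry and the blockMesh vertex mapping

The shipped channel scenario is assembled from three rectangular blocks so
that the injured wall segment is exactly the bottom edge of the middle
block. For users coming from OpenFOAM-style `blockMesh` case setups, the
table below maps the 2D block description used here to the equivalent
blockMesh vertex layout (a 2D slice of the three-block, 16-vertex
arrangement; the front/back pairs collapse onto the plane). `blockMeshDict`
files themselves are **not** parsed — the mapping is documentation only.

Channel: length L = 240 μm, height H = 60 μm, injury length L_i = 90 μm,
side width s = (L − L_i)/2 = 75 μm.

```
 8 ---- 9 ---------- 10 ---- 11        y = H
 |  B0  |     B1      |  B2  |
 0 ---- 1 ----------- 2 ---- 3        y = 0
 x=0   x=s         x=s+L_i  x=L
```

| thrombosim block | extent (μm)          | blockMesh vertices (2D slice) | bottom edge patch |
|------------------|----------------------|-------------------------------|-------------------|
| `blocks[0]` (B0) | [0, 75] × [0, 60]    | 0-1-9-8                       | `walls`           |
| `blocks[1]` (B1) | [75, 165] × [0, 60]  | 1-2-10-9                      | `injuryWalls`     |
| `blocks[2]` (B2) | [165, 240] × [0, 60] | 2-3-11-10                     | `walls`           |

Patch assignment in the case generator:

```python
assignments = {
    (0, "left"): "inlet",  (2, "right"): "outlet",
    (0, "top"): "walls",   (1, "top"): "walls",   (2, "top"): "walls",
    (0, "bottom"): "walls", (2, "bottom"): "walls",
    (1, "bottom"): "injuryWalls",
}
```

Shared block edges (x = 75 and x = 165) are interior interfaces; the
builder rejects any discretization mismatch across them, mirroring the
conformity requirement of a merged blockMesh. The reactive boundary
conditions and the subendothelium-bound enzyme live exclusively on
`injuryWalls`, and the mesh validator additionally checks that every cell
within a platelet diameter (3 μm) of that patch is no wider or taller than
a platelet diameter.
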