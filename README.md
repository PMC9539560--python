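# rootqsm

Cylinder-based quantitative structure models (QSMs) and architectural
trait catalogues for 3D X-ray CT scans of plant roots, with temporal
registration of repeated scans of the same plant.

X-ray CT makes it possible to digitize root system architecture (RSA)
non-invasively: the soil–root segmentation step hands you a
triangulated surface mesh (STL) of the root. `rootqsm` turns such a
mesh into a **QSM** — a tree of circular cylinders with parent/child
topology — and from it computes a six-sheet catalogue of traits:
whole-root totals, per-ramification-order totals, the taproot taper
function, the horizontal spread matrix (10 depth layers × 18 azimuth
directions), and cylinder distributions in diameter / depth / zenith /
azimuth classes.  For weekly scan series it registers the scans
(coarse point-pair alignment + trimmed iterative closest point) and
quantifies growth as spread-matrix differences and trait time series.

The single user parameter is the **scale factor (SF)**: input
coordinates are multiplied by SF, while all internal geometric
constants (surface patch size, minimum cylinder length) are fixed in
scaled units.  A larger SF therefore produces a relatively finer model.
Physical traits are recovered by the unit rules
`[L] = ud/SF`, `[A] = ud²/SF²`, `[V] = ud³/SF³` (`ud` = input unit,
assumed centimetres).  A practical rule: choose SF so the scaled root
is 10–30 units deep.

Reconstruction is stochastic (the surface cover is seeded randomly),
so several models are built per scan and the **median model** — the one
whose total volume is the sample median — is reported.  Robustness
across SF choices is summarized with the median and the normalized
median absolute deviation, `NMAD = 1.4826 · median(|xᵢ − median(x)|)`,
which matches the standard deviation under a Gaussian.

A synthetic-root generator (`rootqsm.synthetic_root`) produces
branching tube meshes with exact closed-form ground truth (volume,
area, length, branch counts, growth series, applied rigid
perturbations), so the whole pipeline is testable without any scan
data.

## Worked example

```python
import rootqsm as rq

# a synthetic taprooted plant: 20 cm taproot tapering 0.4 -> 0.15 cm,
# six laterals of 3-6 cm, exact ground truth from the skeleton
spec = rq.default_spec(seed=0)
mesh, truth = rq.generate_mesh(spec)

cloud = rq.mesh_to_pointcloud(mesh, sf=1.0)     # 20 scaled units deep
qsm = rq.reconstruct(cloud, seed=10)
tt = rq.total_traits(qsm)
print(f"volume {tt.volume:.2f} cm^3 (truth {truth['volume']:.2f})")
print(f"length {tt.length:.1f} cm (truth {truth['length']:.1f})")
print(f"laterals {tt.n_ramifications} (truth {truth['n_ramifications']})")
```

prints

```
volume 7.11 cm^3 (truth 7.00)
length 45.0 cm (truth 47.5)
laterals 6 (truth 6)
```

i.e. total volume and length within a few percent of the analytic
skeleton values and the exact number of lateral roots; the remaining
gap is the cylinder-chain discretization of the tapering, branching
tube.

From the shell, the same pipeline:

```bash
rootqsm synth --seed 0 --out scan.stl          # synthetic scan + truth JSON
rootqsm run --in scan.stl --sf 1.0 --runs 5 --seed 42 --out results/
rootqsm temporal --in w1.stl --in w2.stl --in w3.stl --sf 1.0 \
    --overlaps 0.35,0.40 --rotation-only
```

`rootqsm run` writes `traits.xlsx` (sheets TotalTraits, OrderTraits,
TaprootTaper, Spread, CylinderDist, LateralDist — or one CSV per sheet
with `--fmt csv`), the QSM as `qsm.csv` (one row per cylinder), and a
provenance JSON that makes the run replayable.

## Package layout

| module | contents |
|---|---|
| `geometry_io` | STL reading (binary/ASCII), curvature-change sampling, SF scaling, XYZ/PLY point clouds |
| `segmentation` | cover sets (seeded ball cover), base detection, level-set region growing into a segment tree |
| `cylinder_model` | robust least-squares cylinder fitting, gap filling, QSM assembly and CSV interchange |
| `traits` | the six trait sheets: totals, order table, taper, spread, class distributions, root-ball hulls and alpha shapes |
| `temporal` | Procrustes coarse alignment, trimmed ICP (optionally rotation-only), growth spread deltas |
| `robust_stats` | median/NMAD summaries, median-model selection, the SF sweep protocol |
| `synthetic_root` | ground-truthed branching tube generator, growth series, speckle noise |
| `report` / `cli` | run driver, workbook writer, `rootqsm` command line |
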