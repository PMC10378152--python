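# marrowspat

Spatial point-pattern statistics for multiplex-immunofluorescence (mIF)
cell tables of bone-marrow biopsies across the plasma-cell disease
spectrum (MGUS → smoldering myeloma → multiple myeloma).

Malignant transition in myeloma is accompanied by a change in spatial
organization: tumor (CD138+) cells switch from diffuse infiltration to
focal micro-clusters, T cells accumulate at cluster edges while CD68+
myeloid cells infiltrate freely, and T cell density forms gradients
emanating from CLEC9A+ dendritic-cell hotspots.  `marrowspat` turns
those observations into reusable, tested estimators over per-cell
coordinate tables (as exported by inForm/HALO-style phenotyping):

- **CD138 proximity score** — max over tumor cells of the number of
  other CD138+ cells within a fixed radius r (closed ball, self
  excluded, no edge correction); presets r = 1,000 μm and 100 μm.  An
  indirect, threshold-free measure of tumor clustering:
  `S(r) = max_i #{ j ≠ i : ‖x_i − x_j‖ ≤ r }` over CD138+ cells.
- **NN-distance dispersion** — sample SD of within-phenotype
  nearest-neighbor distances; contrasts nonuniform T cell infiltrates
  with the uniform myeloid compartment.
- **Tumor micro-cluster delineation + exclusion index** — DBSCAN-style
  density clustering with alpha-shape core polygons;
  `EI = (density inside cores) / (density in the peritumoral band)`;
  EI ≪ 1 = exclusion, ≈ 1 = free infiltration.
- **DC-hotspot gradients** — Gaussian-KDE hotspot detection, automated
  proximal/mid/distal zoning along a gradient axis with perpendicular
  cross-gradient controls, per-zone densities and fold changes, and
  marker fractions by zone (e.g. Ki67+ among CD3+).
- **Cross-phenotype proximity** — nearest-neighbor summaries and the
  directed max–min (Hausdorff) distance, e.g. CLEC9A+ → CD3+TCF1+.
- **Exact group statistics** — Mann-Whitney U with full small-sample
  enumeration, permutation tests on mean differences.
- **Virtual-biopsy generator** — marked point processes (CSR, Thomas
  clusters, DC hotspots with planar T cell gradients, hard exclusion
  with edge re-sampling) with per-layer seed substreams and ground-truth
  sidecars, so every estimator is verifiable against planted structure.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```python
import marrowspat as ms

w = ms.Window.from_bounds(0, 0, 4000, 4000)   # 16 mm², coordinates in μm
mm = ms.simulate_marrow(ms.SimulationConfig(
    window=w, seed=11, tumor_mode="clustered",
    tcell_intensity=2000.0, myeloid_intensity=500.0,
    hotspot=ms.HotspotConfig(center=(600, 2000), n_dc=25, dc_sd=40),
    gradient_tau=400.0, exclusion=ms.ExclusionConfig())).table
mgus = ms.simulate_marrow(ms.SimulationConfig(
    window=w, seed=11, tumor_mode="diffuse", tcell_intensity=500.0)).table

for name, t in (("MM-like", mm), ("MGUS-like", mgus)):
    print(name,
          ms.cd138_proximity_score(t, 1000).score,
          ms.cd138_proximity_score(t, 100).score,
          round(ms.nn_distance_dispersion(t, ms.marker("CD3")).sd, 1),
          round(ms.nn_distance_dispersion(t, ms.marker("CD68")).sd, 1))

clusters = ms.delineate_clusters(mm, ms.marker("CD138"))
print(len(clusters),
      ms.exclusion_index(mm, clusters, ms.marker("CD3")).pooled_ei,
      round(ms.exclusion_index(mm, clusters, ms.marker("CD68")).pooled_ei, 2))

hs = ms.detect_hotspots(mm, ms.marker("CLEC9A"), h=50.0)
part = ms.partition_zones(w, hs.hotspots[0])
gr = ms.zone_densities(mm, part, ms.marker("CD3"))
print([round(v, 2) for v in gr.gradient["fold_change"]],
      [round(v, 2) for v in gr.cross["fold_change"]])
```

Output:

```
MM-like 3523 234 15.9 11.9
MGUS-like 1667 32 11.6 11.9
97 0.0 1.05
[1.0, 0.09, 0.03] [1.0, 0.97, 0.92]
```

Reading the numbers: the clustered (MM-like) biopsy's proximity score is
3,523 at r = 1,000 μm and 234 at r = 100 μm, versus 1,667 and 32 for the
diffuse (MGUS-like) biopsy at comparable total cellularity — clustering
concentrates tumor cells into dense neighborhoods at both scales.  The
T cell NN-distance SD is inflated in the MM-like sample (15.9 vs
11.6 μm) while the uniformly infiltrating myeloid compartment is
unchanged (11.9 μm).  Across the 97 delineated micro-clusters, T cells
are fully excluded from cluster cores (pooled EI = 0.0) while myeloid
cells infiltrate freely (EI = 1.05).  The detected DC hotspot carries a
steep T cell gradient (fold changes 1.0 → 0.09 → 0.03 from proximal to
distal zone) while the cross-gradient control stays flat
(1.0 → 0.97 → 0.92).

## Command line

```sh
marrowspat simulate  --config sim.yaml --out cells.tsv --truth truth.tsv
marrowspat proximity --table cells.tsv --radius 1000 --radius 100
marrowspat exclusion --table cells.tsv --phenotype 'CD3+'
marrowspat gradient  --table cells.tsv --query 'CD3+'
marrowspat report    --config pipeline.yaml --outdir report/
```

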