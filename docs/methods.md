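# Methods

`marrowspat` quantifies spatial structure in per-cell coordinate tables
from multiplex-immunofluorescence (mIF) imaging of bone-marrow biopsies
across the plasma-cell disease spectrum (MGUS → SMM → MM).  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Data model

A sample is a **cell table**: one row per segmented cell with continuous
x/y coordinates in μm (origin arbitrary; pixel→μm conversion is the
caller's responsibility) and one boolean positivity flag per marker in
the panel.  The analysis region (**window**) is a simple polygon in μm;
when no ROI is supplied, the tight bounding box of the cells stands in
for it, reflecting whole-slide analyses without an explicit mask.  The
window is treated as a closed set: boundary cells are inside.  Densities
are cells/mm².  Phenotypes are boolean combinations of marker literals
(e.g. `CD3+ & TCF1+`); positivity strings from phenotyping exports
(`pos`/`neg`, `1`/`0`, `true`/`false`, `+`/`-`, `yes`/`no`) are
normalized by a fixed table and unrecognized tokens are errors, never
silently negative.

## Spatial statistics

**Fixed-radius neighbor counts and the CD138 proximity score.**  For
each cell matching a query, the number of *other* matching cells within
a closed Euclidean ball (ties at exactly the radius included).  The
CD138 proximity score is the maximum count over CD138+ cells, at a
default radius of 1,000 μm with a 100 μm preset for tight
micro-clustering.  The index cell is excluded from its own count
(switchable); no edge correction is applied anywhere — closed-form
checks in the test suite use toroidal geometry instead of correcting the
estimators.  A table with no CD138+ cells yields an explicitly undefined
score, not 0.

**Nearest-neighbor distances.**  Per from-cell distance to the nearest
to-cell, with identity-based self-exclusion when a cell matches both
queries (coincident *distinct* cells legitimately yield 0).  The
within-phenotype dispersion statistic is the sample SD (ddof = 1) of NN
distances: uniform infiltrates (myeloid CD68+) have tight NN
distributions, patchy T cell infiltration inflates the SD.  NN distances
are the default reading of "intercellular distances"; all-pairs
distances are available as an option.

**Directed max–min (directed Hausdorff) distance.**  Max over from-cells
of the distance to the nearest to-cell.  The DC–T readout is
CLEC9A+ → CD3+TCF1+ by default (each DC's nearest stem-like T cell,
maximized over DCs); the reverse direction and the symmetric Hausdorff
are exposed, and the direction used is recorded in output metadata since
the choice is a convention.

**Tumor micro-cluster delineation.**  Density-based clustering with
DBSCAN semantics: a core point has ≥ `min_size` neighbors (itself
included) within `eps`; clusters are connected components of core
points; border points join the lowest-id neighboring cluster.  The
implementation is in-package (KD-tree + connected components) so that
memberships are independent of input row order and tie-breaks are
deterministic; cluster ids are canonically ordered by core-centroid
(x, y).  Each cluster's core polygon is its alpha shape (union of
Delaunay triangles with circumradius ≤ `alpha`), falling back to the
convex hull whenever the alpha shape is degenerate or fails to cover
every member, and clipped to the window.  The concave hull is preferred
because convex hulls of irregular micro-clusters swallow empty marrow
and bias interior densities low.  Defaults — `eps` 30 μm, `min_size`
10, `alpha` 50 μm — are order-of-magnitude choices from cell size
(10–15 μm) and the visual scale of micro-clusters; with these settings
clusters are detectable once local tumor density reaches roughly
3,500 cells/mm² (`min_size`/π·eps²), i.e. packed micro-clusters rather
than diffuse infiltrate, which is the intended contrast.

**Exclusion index.**  For a phenotype and a delineated cluster set,

    EI = (count inside cores / core area) / (count in peritumoral band / band area)

where the band is the outward buffer of width `w` (default 50 μm) of
each core, minus all cores, clipped to the window.  EI ≈ 1 means free
infiltration, EI ≪ 1 exclusion with edge accumulation; EI is flagged
undefined when the band holds no phenotype cells.  Pooled EI uses total
counts over union geometries, weighting large clusters more.  EI is an
artifact-defined quantity: "tumor edge" has no standard quantitative
definition, and the band width is the operative choice.  EI is invariant
under uniform rescaling of coordinates when `eps`, `alpha` and `w` scale
along.

**DC hotspots and gradient zones.**  Hotspots are connected
super-threshold components of an (unnormalized) Gaussian KDE of DC
positions — bandwidth `h` (50 μm default), grid step `h`/4, threshold
`rel_threshold` (0.25) × KDE max — that contain ≥ `min_dc` (5) DCs.
The hotspot polygon is the union of super-threshold grid cells; the
centroid is the mean of member DC coordinates.  Around one hotspot the
window is split into `n_zones` (3: proximal/mid/distal) bands of equal
extent perpendicular to a gradient axis, plus the same construction
parallel to the axis as cross-gradient controls; the hotspot region is
cut out of every zone.  "Roughly equal" is interpreted as equal extent
along the partition direction, not equal area — simpler and
order-preserving, and per-zone areas are always reported.  The axis
defaults to hotspot-centroid → window-centroid, an automated stand-in
for the manual choice of gradient direction in the original workflow;
it is user-overridable and recorded in the output.  Cells are assigned
to zones by half-open binning of their axis coordinate, so zone counts
plus the hotspot count always sum exactly to the total.  Fold changes
are densities relative to the first (proximal) zone of each family and
are flagged undefined when the proximal density is zero.

**Group statistics.**  Mann-Whitney U with midranks; the p-value comes
from full enumeration of all C(n+m, n) labelings while that count is
≤ 10⁶ (two-sided: deviation of U from nm/2 at least as large as
observed), and otherwise from the tie-corrected normal approximation.
A two-sided permutation test on the difference of means, with the
add-one rule (p ≥ 1/(n_perm+1)), serves as the distribution-free
analogue of Welch-type contrasts.  Reports therefore reproduce
qualitative group orderings, not any particular parametric p-value.
Benjamini–Hochberg flagging across metrics is available but off by
default, matching per-figure testing practice.

## The virtual-biopsy generator

No patient-level cell tables are deposited for this disease setting, so
every stage is verified against simulated biopsies with known ground
truth.  The generator is a marked point process in a 2×2 mm window by
default:

| layer | model | default |
| --- | --- | --- |
| tumor (CD138+), clustered | Thomas process: Poisson parents, Poisson(μ_off) offspring, isotropic Gaussian scatter | κ = 2.5 /mm², μ_off = 250, σ_off = 100 μm |
| tumor, diffuse | homogeneous Poisson (CSR) | 500 /mm² |
| myeloid (CD68+) | CSR | 500 /mm² |
| T cells (CD3+) | CSR thinned by the gradient, optionally excluded from cores | 800 /mm² (dominating) |
| DCs (CLEC9A+) | n_dc points ~ N(center, dc_sd²·I) | n_dc = 20, dc_sd = 50 μm |

Clustered-mode defaults were chosen once so that micro-clusters sit in
the packed regime (peak blob density ≈ 4,000 cells/mm²) that the
delineation defaults are built for; τ = 200 μm, band width w = 50 μm
and σ_off = 100 μm are scale placeholders for a cluster/gradient
geometry that the field has not measured quantitatively.

**Gradient.**  With decay length τ set, T cells are accepted with
probability exp(−max(0, (p−c)·û)/τ), where c is the hotspot center and
û the gradient axis (default: toward the window centroid).  The decay
is *planar* (along the axis) rather than radial: a radial decay makes
the cross-gradient control bands systematically unequal (the middle
band contains the hotspot and its flanks), which contradicts the
flat-control behavior the analysis is designed to detect.  Planar decay
produces exactly the intended structure — monotone fold changes along
the gradient, flat fold changes across it.  A Ki67+ fraction among T
cells may decay with the same geometry (`ki67_tau`), emulating a
proliferation gradient; TCF1+ is an independent Bernoulli mark.

**Exclusion.**  With exclusion on, tumor cores are delineated with the
same clustering the analysis uses; T cells landing inside a core are
rejected and re-sampled uniformly into the peritumoral band, producing
edge accumulation with a single parameter (band width).

**Determinism.**  Every layer draws from a named substream
(`SeedSequence(seed, spawn_key=(k,))`) of the root seed, so output is
bitwise reproducible and adding or removing a layer never perturbs the
others.  Offspring and thinned points outside the window are discarded
(no toroidal wrap); toroidal geometry appears only in test oracles,
where it makes the 2D Poisson closed forms (mean NN distance 1/(2√λ),
NN CV √((4−π)/π), mean ball count λπr²) exact.

**What the simulations do not emulate:** marker intensity
distributions, segmentation noise, 3D tissue context, bone/fat
morphology, spatial inhomogeneity of the marrow itself, and biological
correlations between layers beyond the planted gradient/exclusion
structure.  Passing recovery tests therefore shows that the estimators
detect the structure they target at realistic densities — not that
patient tissue satisfies the generative assumptions.

## Numerical choices and degenerate inputs

- Distances are exact Euclidean via KD-trees; all metrics agree exactly
  with O(n²) brute-force oracles (tested on 100 random instances).
- Empty query sets raise explicit errors for distance statistics; an
  empty CD138+ set yields an undefined (not zero) proximity score;
  fewer tumor cells than `min_size` yields an empty cluster set, not an
  error.
- Collinear clusters get a hair-width buffered hull so core polygons
  always have positive area; zone/EI ratios with zero denominators are
  flagged undefined (NaN), never coerced to 0.
- Degenerate gradient axes (hotspot at the window centroid) require an
  explicit axis.
- Pipeline reports use fixed column order, fixed float formatting and
  sorted JSON keys, so identical config + seed reproduces output byte
  for byte.

## Problem sizes used in verification

Recovery experiments run 100 independent seeds per condition on 2×2 mm
(gradient, exclusion) or 4×4 mm (proximity discrimination) windows with
the default intensities above — a few thousand cells per biopsy,
matching the per-ROI scale of mIF analyses.  Closed-form CSR checks use
λ·area = 4,000 points on a 2×2 mm torus.

## Known limitations

- 2D only; no serial-section tracking or 3D clustering.
- No edge-corrected estimators (Ripley's K, pair correlation) — the
  statistics here are the bespoke readouts, deliberately uncorrected.
- The gradient axis automation (KDE hotspot + centroid-directed axis)
  replaces a manual segmentation step; a manual-polygon path via
  explicit `Hotspot` objects and `axis=` overrides reproduces the
  manual workflow.
- Exact Mann-Whitney enumeration is O(C(n+m, n)) and switches to the
  normal approximation above 10⁶ arrangements.
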