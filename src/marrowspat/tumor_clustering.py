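"""Tumor micro-cluster delineation and immune-exclusion quantification.

Malignant plasma cells grow in focal micro-clusters rather than diffusely.
This module delineates those clusters from CD138+ coordinates by
density-based clustering (DBSCAN semantics), draws a concave (alpha-shape)
core polygon per cluster, and quantifies immune exclusion as the ratio of a
phenotype's density inside cluster cores to its density in the peritumoral
band:

    EI = (count inside cores / core area) / (count in band / band area)

EI ≪ 1 means the phenotype accumulates at the tumor edge but is depleted
inside (T cell exclusion); EI ≈ 1 means free infiltration (the myeloid
pattern).

The DBSCAN step is implemented here rather than delegated so that cluster
memberships are independent of input row order and border-point ties break
deterministically to the lowest cluster id.  Default parameters (eps 30 μm,
min_size 10, alpha 50 μm, band width 50 μm) are order-of-magnitude choices
from cell size (~10–15 μm) and visual micro-cluster scale; all are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .cell_table_io import CellTable, PhenotypeQuery, ValidationError, Window

__all__ = [
    "Cluster",
    "ClusterSet",
    "ExclusionReport",
    "delineate_clusters",
    "classify_relative_position",
    "exclusion_index",
    "DEFAULT_EPS_UM",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_ALPHA_UM",
    "DEFAULT_BAND_WIDTH_UM",
]

DEFAULT_EPS_UM = 30.0
DEFAULT_MIN_SIZE = 10
DEFAULT_ALPHA_UM = 50.0
DEFAULT_BAND_WIDTH_UM = 50.0

_ZONE_LABELS = ("interior", "edge_band", "exterior")


@dataclass
class Cluster:
    """One delineated tumor micro-cluster."""

    cluster_id: int
    member_ids: list[str]
    polygon: shapely.Geometry  # core polygon clipped to the window
    area_mm2: float


@dataclass
class ClusterSet:
    """All clusters plus unclustered (noise) tumor cells and the parameters used."""

    clusters: list[Cluster]
    noise_ids: list[str]
    parameters: dict

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def core_union(self) -> shapely.Geometry:
        if not self.clusters:
            return Polygon()
        return unary_union([c.polygon for c in self.clusters])


@dataclass
class ExclusionReport:
    """Interior vs peritumoral-band densities and exclusion indices.

    ``per_cluster`` has one row per cluster (interior/band counts, areas in
    mm², ``ei`` NaN where the band holds no phenotype cells).  Pooled values
    use total counts over union geometries, so large clusters weigh more.
    """

    per_cluster: pd.DataFrame
    pooled_ei: float
    pooled_interior_count: int
    pooled_interior_area_mm2: float
    pooled_band_count: int
    pooled_band_area_mm2: float
    band_width: float
    phenotype: str
    pooled_undefined: bool = False


# ---------------------------------------------------------------------------
# Density-based clustering (deterministic DBSCAN)
# ---------------------------------------------------------------------------


def _dbscan_labels(points: np.ndarray, eps: float, min_size: int) -> np.ndarray:
    """DBSCAN labels (-1 = noise), independent of point order.

    Core point: at least ``min_size`` points (itself included) within eps.
    Clusters are connected components of core points; border points join
    the lowest-id neighboring cluster.  Cluster ids are canonicalized by
    sorting core-point centroids lexicographically by (x, y).
    """
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighbor_counts = tree.query_ball_point(points, r=eps, return_length=True)
    core = neighbor_counts >= min_size
    core_idx = np.flatnonzero(core)
    if core_idx.size == 0:
        return labels

    core_tree = cKDTree(points[core_idx])
    pairs = core_tree.query_pairs(eps, output_type="ndarray")
    m = len(core_idx)
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    _, comp = connected_components(adj, directed=False)

    # canonical ordering: components sorted by centroid (x, y)
    order = sorted(
        range(comp.max() + 1),
        key=lambda c: tuple(points[core_idx[comp == c]].mean(axis=0)),
    )
    rank = {c: i for i, c in enumerate(order)}
    labels[core_idx] = [rank[c] for c in comp]

    # border points: non-core with a core neighbor; ties → lowest cluster id
    border_idx = np.flatnonzero(~core)
    if border_idx.size:
        neighbor_lists = tree.query_ball_point(points[border_idx], r=eps)
        for i, nbrs in zip(border_idx, neighbor_lists):
            core_nbr_labels = labels[[j for j in nbrs if core[j]]]
            if core_nbr_labels.size:
                labels[i] = int(core_nbr_labels.min())
    return labels


def _alpha_shape(points: np.ndarray, alpha: float) -> Optional[shapely.Geometry]:
    """Union of Delaunay triangles with circumradius ≤ alpha; None if degenerate."""
    if len(points) < 3:
        return None
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    keep = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        if area2 <= 0:
            continue
        circumradius = la * lb * lc / (2.0 * area2)
        if circumradius <= alpha:
            keep.append(Polygon(points[simplex]))
    if not keep:
        return None
    geom = unary_union(keep)
    if geom.is_empty or geom.area <= 0:
        return None
    return geom


def _core_polygon(points: np.ndarray, alpha: float, window: Window) -> shapely.Geometry:
    """Concave core polygon for a cluster, clipped to the window.

    Falls back to the convex hull when the alpha shape is degenerate or
    fails to cover every member (stray vertices of discarded slivers), so
    the containment invariant always holds.
    """
    geom = _alpha_shape(points, alpha)
    if geom is not None:
        member_pts = shapely.points(points[:, 0], points[:, 1])
        if not shapely.covers(geom, member_pts).all():
            geom = None
    if geom is None:
        geom = MultiPoint(points).convex_hull
        if geom.area <= 0:  # collinear cluster: give it a hair of width
            geom = geom.buffer(1e-6)
    clipped = geom.intersection(window.polygon)
    if clipped.is_empty or clipped.area <= 0:
        clipped = geom
    return clipped


def delineate_clusters(
    table: CellTable,
    tumor_query: PhenotypeQuery,
    eps: float = DEFAULT_EPS_UM,
    min_size: int = DEFAULT_MIN_SIZE,
    alpha: float = DEFAULT_ALPHA_UM,
) -> ClusterSet:
    """Delineate tumor micro-clusters and their core polygons.

    Fewer tumor cells than ``min_size`` yields an empty ClusterSet (not an
    error): diffuse MGUS-like marrow legitimately has no clusters.
    """
    if eps <= 0:
        raise ValidationError(f"eps must be positive, got {eps}")
    if min_size < 3:
        raise ValidationError(f"min_size must be at least 3, got {min_size}")
    mask = table.mask(tumor_query)
    pts = table.coords()[mask]
    ids = np.asarray(table.df.loc[mask, "cell_id"].tolist(), dtype=object)
    params = {"eps": float(eps), "min_size": int(min_size), "alpha": float(alpha),
              "tumor_query": str(tumor_query)}
    labels = _dbscan_labels(pts, eps, min_size)
    clusters: list[Cluster] = []
    for cid in range(labels.max() + 1 if labels.size else 0):
        sel = labels == cid
        poly = _core_polygon(pts[sel], alpha, table.window)
        clusters.append(
            Cluster(
                cluster_id=cid,
                member_ids=list(ids[sel]),
                polygon=poly,
                area_mm2=float(poly.area) / 1e6,
            )
        )
    noise_ids = list(ids[labels == -1])
    return ClusterSet(clusters=clusters, noise_ids=noise_ids, parameters=params)


# ---------------------------------------------------------------------------
# Relative position and exclusion index
# ---------------------------------------------------------------------------


def classify_relative_position(
    table: CellTable,
    clusters: ClusterSet,
    band_width: float = DEFAULT_BAND_WIDTH_UM,
) -> np.ndarray:
    """Per-cell zone label: ``interior`` | ``edge_band`` | ``exterior``.

    Interior = inside (or on the boundary of) some cluster core; edge band
    = outside every core but within ``band_width`` μm of one; exterior
    otherwise.  With no clusters every cell is exterior.
    """
    if band_width <= 0:
        raise ValidationError(f"band_width must be positive, got {band_width}")
    n = len(table)
    labels = np.full(n, "exterior", dtype=object)
    if not clusters.clusters or n == 0:
        return labels
    union = clusters.core_union
    pts = shapely.points(table.df["x"].to_numpy(), table.df["y"].to_numpy())
    interior = shapely.covers(union, pts)
    near = shapely.dwithin(union, pts, band_width)
    labels[interior] = "interior"
    labels[near & ~interior] = "edge_band"
    return labels


def _band_geometry(core: shapely.Geometry, all_cores: shapely.Geometry,
                   window: Window, w: float) -> shapely.Geometry:
    """Peritumoral band: outward buffer minus every core, clipped to the window."""
    return core.buffer(w).difference(all_cores).intersection(window.polygon)


def exclusion_index(
    table: CellTable,
    clusters: ClusterSet,
    phenotype: PhenotypeQuery,
    band_width: float = DEFAULT_BAND_WIDTH_UM,
) -> ExclusionReport:
    """Interior vs peritumoral-band density ratio for one phenotype.

    Per cluster and pooled (total counts over union areas).  EI is NaN
    (flagged) wherever the band density is zero.
    """
    if not clusters.clusters:
        raise ValidationError("exclusion_index requires a non-empty ClusterSet")
    if band_width <= 0:
        raise ValidationError(f"band_width must be positive, got {band_width}")
    mask = table.mask(phenotype)
    pts = shapely.points(
        table.df.loc[mask, "x"].to_numpy(), table.df.loc[mask, "y"].to_numpy()
    )
    all_cores = clusters.core_union
    rows = []
    for c in clusters.clusters:
        band = _band_geometry(c.polygon, all_cores, table.window, band_width)
        interior_count = int(shapely.covers(c.polygon, pts).sum())
        band_count = int(shapely.covers(band, pts).sum())
        interior_area = float(c.polygon.area) / 1e6
        band_area = float(band.area) / 1e6
        interior_density = interior_count / interior_area if interior_area > 0 else np.nan
        band_density = band_count / band_area if band_area > 0 else np.nan
        undefined = not (band_density and np.isfinite(band_density))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "interior_count": interior_count,
                "interior_area_mm2": interior_area,
                "band_count": band_count,
                "band_area_mm2": band_area,
                "interior_density_mm2": interior_density,
                "band_density_mm2": band_density,
                "ei": np.nan if undefined else interior_density / band_density,
                "undefined": undefined,
            }
        )
    pooled_interior = all_cores.intersection(table.window.polygon)
    pooled_band = all_cores.buffer(band_width).difference(all_cores).intersection(
        table.window.polygon
    )
    pooled_int_count = int(shapely.covers(pooled_interior, pts).sum())
    pooled_band_count = int(shapely.covers(pooled_band, pts).sum())
    pooled_int_area = float(pooled_interior.area) / 1e6
    pooled_band_area = float(pooled_band.area) / 1e6
    pooled_undefined = pooled_band_count == 0 or pooled_band_area <= 0 or pooled_int_area <= 0
    if pooled_undefined:
        pooled_ei = float("nan")
    else:
        pooled_ei = (pooled_int_count / pooled_int_area) / (
            pooled_band_count / pooled_band_area
        )
    return ExclusionReport(
        per_cluster=pd.DataFrame(rows),
        pooled_ei=pooled_ei,
        pooled_interior_count=pooled_int_count,
        pooled_interior_area_mm2=pooled_int_area,
        pooled_band_count=pooled_band_count,
        pooled_band_area_mm2=pooled_band_area,
        band_width=float(band_width),
        phenotype=str(phenotype),
        pooled_undefined=pooled_undefined,
    )
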