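"""Virtual bone-marrow biopsies as marked point processes.

No patient cell tables are publicly deposited, so every analysis stage is
exercised against synthetic biopsies whose ground truth is known.  The
generator reproduces the statistical structure the analyses assume:

* **Tumor (CD138+)** — either diffuse (homogeneous Poisson / CSR, the
  MGUS-like pattern) or clustered (Thomas parent–offspring process with
  Gaussian offspring scatter, the MM-like focal micro-cluster pattern).
* **Myeloid (CD68+)** — always diffuse (CSR), matching the diffusely
  distributed myeloid infiltrate.
* **DC hotspot (CLEC9A+)** — a fixed number of DCs Gaussian-scattered
  about a hotspot center.
* **T cells (CD3+)** — a dominating CSR layer thinned so that density
  decays with length scale τ along the gradient axis away from the
  hotspot, and optionally excluded from tumor-cluster cores with the
  rejected mass re-sampled into the peritumoral band.  Fractions of T
  cells are flagged TCF1+ and Ki67+ (the Ki67+ fraction may itself decay
  with distance from the hotspot).

All layers draw from named substreams of one root seed, so adding or
removing a layer never perturbs the others, and every generator is a pure
function of (config, seed).  Points falling outside the window are
discarded (no toroidal wrap); intensities are cells/mm², lengths μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .cell_table_io import CellTable, ValidationError, Window
from .tumor_clustering import (
    DEFAULT_ALPHA_UM,
    DEFAULT_EPS_UM,
    DEFAULT_MIN_SIZE,
    _core_polygon,
    _dbscan_labels,
)

__all__ = [
    "HotspotConfig",
    "ExclusionConfig",
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "layer_rng",
    "simulate_csr",
    "simulate_thomas",
    "simulate_marrow",
    "MARKERS",
]

#: Marker panel carried by every simulated table.
MARKERS = ("CD138", "CD68", "CD3", "CLEC9A", "TCF1", "Ki67")

#: Named substreams of the root seed, one per simulation layer.
_STREAMS = {"tumor": 0, "myeloid": 1, "tcell": 2, "dc": 3, "marks": 4, "exclusion": 5}


def layer_rng(seed: int, layer: str) -> np.random.Generator:
    """Independent generator for one simulation layer of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[layer],))
    )


@dataclass(frozen=True)
class HotspotConfig:
    """A CLEC9A+ DC hotspot: ``n_dc`` DCs scattered N(center, dc_sd²·I)."""

    center: tuple[float, float]
    n_dc: int = 20
    dc_sd: float = 50.0


@dataclass(frozen=True)
class ExclusionConfig:
    """T cell exclusion from tumor-cluster cores.

    T cells landing inside a delineated core are rejected and re-sampled
    uniformly into the peritumoral band of width ``band_width`` μm.  The
    cores are delineated with the same density-based clustering the
    analysis uses (parameters below).
    """

    band_width: float = 50.0
    eps: float = DEFAULT_EPS_UM
    min_size: int = DEFAULT_MIN_SIZE
    alpha: float = DEFAULT_ALPHA_UM


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one virtual biopsy.

    Intensities are cells/mm²; lengths μm.  ``tumor_mode`` "diffuse" uses
    ``tumor_intensity``; "clustered" uses the Thomas parameters
    (``parent_intensity`` parents/mm², ``offspring_mean`` expected cells
    per parent, ``offspring_sd`` μm Gaussian scatter).  ``gradient_tau``
    set (requires a hotspot) makes T cell density decay with that length
    scale along the gradient axis (default axis: hotspot center → window
    centroid); absent, T cells are uniform.
    """

    window: Window = field(default_factory=lambda: Window.from_bounds(0, 0, 2000, 2000))
    seed: int = 0
    tumor_mode: str = "clustered"
    tumor_intensity: float = 500.0
    parent_intensity: float = 2.5
    offspring_mean: float = 250.0
    offspring_sd: float = 100.0
    myeloid_intensity: float = 500.0
    tcell_intensity: float = 800.0
    hotspot: Optional[HotspotConfig] = None
    gradient_tau: Optional[float] = None
    gradient_axis: Optional[tuple[float, float]] = None
    exclusion: Optional[ExclusionConfig] = None
    tcf1_fraction: float = 0.4
    ki67_fraction: float = 0.3
    ki67_tau: Optional[float] = None
    sample_id: str = "synthetic"
    group: str = "synthetic"

    def validate(self) -> None:
        if self.tumor_mode not in ("diffuse", "clustered"):
            raise ValidationError(f"unknown tumor_mode {self.tumor_mode!r}")
        for name in ("tumor_intensity", "myeloid_intensity", "tcell_intensity"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tumor_mode == "clustered":
            if min(self.parent_intensity, self.offspring_mean, self.offspring_sd) <= 0:
                raise ValidationError(
                    "clustered mode requires positive parent_intensity, "
                    "offspring_mean and offspring_sd"
                )
        if self.hotspot is not None:
            cx, cy = self.hotspot.center
            if not self.window.contains(cx, cy):
                raise ValidationError(f"hotspot center {self.hotspot.center} outside window")
            if self.hotspot.dc_sd <= 0 or self.hotspot.n_dc < 0:
                raise ValidationError("hotspot needs dc_sd > 0 and n_dc >= 0")
        if self.gradient_tau is not None:
            if self.gradient_tau <= 0:
                raise ValidationError("gradient_tau must be positive")
            if self.hotspot is None:
                raise ValidationError("gradient_tau requires a hotspot")
        if self.exclusion is not None and self.exclusion.band_width <= 0:
            raise ValidationError("exclusion band_width must be positive")
        if not 0 <= self.tcf1_fraction <= 1 or not 0 <= self.ki67_fraction <= 1:
            raise ValidationError("mark fractions must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground-truth annotations emitted alongside the simulated table.

    ``per_cell`` holds one row per emitted cell: layer, parent index (tumor
    offspring in clustered mode, else -1), signed distance along the
    gradient axis past the hotspot center (NaN without a hotspot), and
    whether the cell was re-sampled into the peritumoral band by the
    exclusion step.
    """

    parents: np.ndarray
    hotspot_center: Optional[tuple[float, float]]
    gradient_axis: Optional[tuple[float, float]]
    tumor_core_union: Optional[shapely.Geometry]
    per_cell: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulationResult:
    table: CellTable
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Elementary point processes
# ---------------------------------------------------------------------------


def _uniform_in_window(n: int, window: Window, rng: np.random.Generator,
                       max_iter: int = 1000) -> np.ndarray:
    """n i.i.d. uniform points in the window (rejection from the bbox)."""
    xmin, ymin, xmax, ymax = window.bounds
    out = np.empty((0, 2))
    rect = math.isclose(window.area_um2, (xmax - xmin) * (ymax - ymin))
    for _ in range(max_iter):
        if len(out) >= n:
            break
        need = n - len(out)
        draw = max(need, int(need * 1.5) + 8) if not rect else need
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, draw), rng.uniform(ymin, ymax, draw)]
        )
        if not rect:
            pts = pts[window.covers_xy(pts[:, 0], pts[:, 1])]
        out = np.vstack([out, pts])
    return out[:n]


def simulate_csr(intensity: float, window: Window, seed: int,
                 *, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Homogeneous Poisson (CSR) point pattern at ``intensity`` cells/mm².

    N ~ Poisson(intensity × area); positions i.i.d. uniform; deterministic
    given the seed.
    """
    if intensity < 0:
        raise ValidationError(f"intensity must be >= 0, got {intensity}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * window.area_mm2))
    return _uniform_in_window(n, window, rng)


def simulate_thomas(
    parent_intensity: float,
    offspring_mean: float,
    offspring_sd: float,
    window: Window,
    seed: int,
    *,
    rng: Optional[np.random.Generator] = None,
    return_parents: bool = False,
):
    """Thomas cluster process: Poisson parents, Gaussian-scattered offspring.

    Parents ~ Poisson(parent_intensity × area) uniform in the window; each
    spawns Poisson(offspring_mean) offspring displaced by isotropic
    N(0, offspring_sd²); offspring outside the window are discarded.
    """
    if min(parent_intensity, offspring_mean, offspring_sd) <= 0:
        raise ValidationError("Thomas parameters must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    parents = simulate_csr(parent_intensity, window, seed, rng=rng)
    pts_list = []
    parent_idx = []
    for i, p in enumerate(parents):
        k = int(rng.poisson(offspring_mean))
        if k == 0:
            continue
        off = p + rng.normal(0.0, offspring_sd, size=(k, 2))
        keep = window.covers_xy(off[:, 0], off[:, 1])
        pts_list.append(off[keep])
        parent_idx.append(np.full(int(keep.sum()), i))
    pts = np.vstack(pts_list) if pts_list else np.empty((0, 2))
    pidx = np.concatenate(parent_idx) if parent_idx else np.empty(0, dtype=int)
    if return_parents:
        return pts, parents, pidx
    return pts


# ---------------------------------------------------------------------------
# Composite virtual biopsy
# ---------------------------------------------------------------------------


def _axis_unit(config: SimulationConfig) -> Optional[np.ndarray]:
    if config.hotspot is None:
        return None
    if config.gradient_axis is not None:
        v = np.asarray(config.gradient_axis, dtype=float)
    else:
        cx, cy = config.window.centroid
        v = np.array([cx - config.hotspot.center[0], cy - config.hotspot.center[1]])
    norm = float(np.hypot(*v))
    if norm < 1e-9:
        raise ValidationError(
            "gradient axis is degenerate (hotspot at the window centroid); "
            "set gradient_axis explicitly"
        )
    return v / norm


def _axis_distance(pts: np.ndarray, center: tuple[float, float],
                   unit: np.ndarray) -> np.ndarray:
    """Signed distance along the gradient axis past the hotspot center."""
    return (pts - np.asarray(center)) @ unit


def _sample_in_geometry(n: int, geom: shapely.Geometry, window: Window,
                        rng: np.random.Generator, max_iter: int = 2000) -> np.ndarray:
    """Uniform points in an arbitrary geometry via bbox rejection."""
    if n == 0 or geom.is_empty or geom.area <= 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = geom.bounds
    frac = max(geom.area / ((xmax - xmin) * (ymax - ymin)), 1e-4)
    out = np.empty((0, 2))
    for _ in range(max_iter):
        if len(out) >= n:
            break
        need = n - len(out)
        draw = int(need / frac) + 8
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, draw), rng.uniform(ymin, ymax, draw)]
        )
        keep = shapely.covers(geom, shapely.points(pts[:, 0], pts[:, 1]))
        out = np.vstack([out, pts[keep]])
    return out[:n]


def simulate_marrow(config: SimulationConfig) -> SimulationResult:
    """Generate one virtual biopsy as a CellTable plus ground truth."""
    config.validate()
    window = config.window
    seed = config.seed

    # --- tumor layer -------------------------------------------------------
    parents = np.empty((0, 2))
    if config.tumor_mode == "clustered":
        tumor, parents, tumor_parent = simulate_thomas(
            config.parent_intensity, config.offspring_mean, config.offspring_sd,
            window, seed, rng=layer_rng(seed, "tumor"), return_parents=True,
        )
    else:
        tumor = simulate_csr(config.tumor_intensity, window, seed,
                             rng=layer_rng(seed, "tumor"))
        tumor_parent = np.full(len(tumor), -1)

    # --- myeloid layer (always diffuse) ------------------------------------
    myeloid = simulate_csr(config.myeloid_intensity, window, seed,
                           rng=layer_rng(seed, "myeloid"))

    # --- DC hotspot ---------------------------------------------------------
    dc = np.empty((0, 2))
    unit = None
    if config.hotspot is not None:
        try:
            unit = _axis_unit(config)
        except ValidationError:
            # only fatal when an axis is actually needed
            if config.gradient_tau is not None or config.ki67_tau is not None:
                raise
    if config.hotspot is not None:
        rng_dc = layer_rng(seed, "dc")
        center = np.asarray(config.hotspot.center)
        pts = []
        while len(pts) < config.hotspot.n_dc:
            cand = center + rng_dc.normal(0.0, config.hotspot.dc_sd, size=2)
            if window.contains(cand[0], cand[1]):
                pts.append(cand)
        dc = np.array(pts) if pts else np.empty((0, 2))

    # --- T cells: dominating CSR, gradient thinning, exclusion --------------
    rng_t = layer_rng(seed, "tcell")
    tcell = simulate_csr(config.tcell_intensity, window, seed, rng=rng_t)
    if config.gradient_tau is not None and len(tcell):
        d_axis = _axis_distance(tcell, config.hotspot.center, unit)
        accept_p = np.exp(-np.maximum(d_axis, 0.0) / config.gradient_tau)
        tcell = tcell[rng_t.uniform(size=len(tcell)) < accept_p]

    core_union = None
    resampled = np.zeros(len(tcell), dtype=bool)
    if config.exclusion is not None and len(tumor):
        exc = config.exclusion
        labels = _dbscan_labels(tumor, exc.eps, exc.min_size)
        cores = [
            _core_polygon(tumor[labels == cid], exc.alpha, window)
            for cid in range(labels.max() + 1 if labels.size else 0)
        ]
        if cores:
            core_union = unary_union(cores)
            band = core_union.buffer(exc.band_width).difference(core_union)
            band = band.intersection(window.polygon)
            if len(tcell):
                inside = shapely.covers(
                    core_union, shapely.points(tcell[:, 0], tcell[:, 1])
                )
                n_reject = int(inside.sum())
                kept = tcell[~inside]
                moved = _sample_in_geometry(
                    n_reject, band, window, layer_rng(seed, "exclusion")
                )
                tcell = np.vstack([kept, moved])
                resampled = np.concatenate(
                    [np.zeros(len(kept), bool), np.ones(len(moved), bool)]
                )

    # --- marks on T cells ----------------------------------------------------
    rng_m = layer_rng(seed, "marks")
    n_t = len(tcell)
    tcf1 = rng_m.uniform(size=n_t) < config.tcf1_fraction
    if config.ki67_tau is not None and config.hotspot is not None and n_t:
        d_axis_t = _axis_distance(tcell, config.hotspot.center, unit)
        p_ki67 = config.ki67_fraction * np.exp(
            -np.maximum(d_axis_t, 0.0) / config.ki67_tau
        )
    else:
        p_ki67 = np.full(n_t, config.ki67_fraction)
    ki67 = rng_m.uniform(size=n_t) < p_ki67

    # --- assemble ------------------------------------------------------------
    layers = [
        ("tum", tumor, {"CD138": True}),
        ("mye", myeloid, {"CD68": True}),
        ("tc", tcell, {"CD3": True}),
        ("dc", dc, {"CLEC9A": True}),
    ]
    frames = []
    truth_rows = []
    for prefix, pts, base_marks in layers:
        n = len(pts)
        if n == 0:
            continue
        df = pd.DataFrame(
            {
                "cell_id": [f"{prefix}{i:05d}" for i in range(n)],
                "x": pts[:, 0],
                "y": pts[:, 1],
            }
        )
        for m in MARKERS:
            df[m] = bool(base_marks.get(m, False))
        if prefix == "tc":
            df["TCF1"] = tcf1
            df["Ki67"] = ki67
        frames.append(df)
        if config.hotspot is not None and unit is not None:
            d_axis_layer = _axis_distance(pts, config.hotspot.center, unit)
        else:
            d_axis_layer = np.full(n, np.nan)
        truth_rows.append(
            pd.DataFrame(
                {
                    "cell_id": df["cell_id"],
                    "layer": {"tum": "tumor", "mye": "myeloid",
                              "tc": "tcell", "dc": "dc"}[prefix],
                    "parent": tumor_parent if prefix == "tum" else -1,
                    "d_axis_um": d_axis_layer,
                    "resampled": resampled if prefix == "tc" else False,
                }
            )
        )
    if frames:
        cells = pd.concat(frames, ignore_index=True)
        truth_df = pd.concat(truth_rows, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["cell_id", "x", "y", *MARKERS])
        truth_df = pd.DataFrame(
            columns=["cell_id", "layer", "parent", "d_axis_um", "resampled"]
        )
    table = CellTable(
        df=cells, window=window, marker_set=MARKERS,
        sample_id=config.sample_id, group=config.group,
    )
    truth = SimulationTruth(
        parents=parents,
        hotspot_center=config.hotspot.center if config.hotspot else None,
        gradient_axis=tuple(unit) if unit is not None else None,
        tumor_core_union=core_union,
        per_cell=truth_df,
        config=config,
    )
    return SimulationResult(table=table, truth=truth)
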