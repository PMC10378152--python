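"""Group-contrast statistics and pipeline report assembly.

Figure-legend statistics in this domain are simple two-group contrasts
(Mann-Whitney U, Welch-type mean comparisons).  To keep the statistical
core of the package self-verifiable, both are implemented with exact or
permutation enumeration:

* :func:`mann_whitney_exact` — the U statistic with midranks; the p-value
  comes from full enumeration of all C(n+m, n) group labelings whenever
  that count is ≤ 10⁶, and otherwise from the tie-corrected normal
  approximation.  Exact enumeration makes the implementation checkable
  against brute force at small n.
* :func:`permutation_mean_diff` — a two-sided permutation test on the
  difference of means (a distribution-free analogue of Welch-type
  contrasts), with the add-one rule so p is never 0.

:func:`run_pipeline` assembles a per-sample metrics table over input or
simulated biopsies, runs group comparisons per metric, and emits a run
manifest; identical config + seed reproduces the report byte for byte.
Reports use these distribution-free tests throughout, so they reproduce
qualitative group orderings rather than any particular parametric
p-value.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .cell_table_io import (
    CellTable,
    PhenotypeQuery,
    ValidationError,
    Window,
    marker,
    read_cell_table,
    read_roi,
)
from .gradient_analysis import detect_hotspots, partition_zones, zone_densities
from .proximity_metrics import (
    CD138_RADIUS_SMALL_UM,
    CD138_RADIUS_UM,
    cd138_proximity_score,
    max_min_distance,
    nn_distance_dispersion,
)
from .synthetic_data import (
    ExclusionConfig,
    HotspotConfig,
    SimulationConfig,
    simulate_marrow,
)
from .tumor_clustering import delineate_clusters, exclusion_index

__all__ = [
    "GroupComparison",
    "mann_whitney_exact",
    "permutation_mean_diff",
    "ConfigError",
    "PipelineConfig",
    "SampleSpec",
    "ReportBundle",
    "run_pipeline",
    "write_report",
    "METRICS",
    "MAX_ENUMERATION",
]

#: Full enumeration of group labelings is used while C(n+m, n) stays below this.
MAX_ENUMERATION = 10**6


class ConfigError(ValidationError):
    """A run configuration references unknown metrics or is malformed."""


@dataclass
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    two_sided: bool
    exact: bool


# ---------------------------------------------------------------------------
# Mann-Whitney U with exact small-sample enumeration
# ---------------------------------------------------------------------------


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(group_a: Sequence[float], group_b: Sequence[float],
                       two_sided: bool = True) -> GroupComparison:
    """Mann-Whitney U test with exact enumeration at small sample sizes.

    Ties are handled by midranks.  The exact two-sided p-value is the
    fraction of all C(n+m, n) labelings whose U deviates from nm/2 by at
    least as much as the observed U; one-sided is the fraction with U at
    least the observed (alternative: group_a stochastically larger).
    Above :data:`MAX_ENUMERATION` arrangements the tie-corrected normal
    approximation is used instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    # double the midranks so every rank is integral and comparisons are exact
    ranks2 = np.rint(sps.rankdata(pooled) * 2).astype(np.int64)
    u_obs2 = ranks2[:n].sum() - n * (n + 1)  # 2·U_a
    total2 = 2 * n * m  # 2·(U_a + U_b) = 2nm

    if comb(n + m, n) <= MAX_ENUMERATION:
        dev_obs = abs(2 * u_obs2 - total2)  # |U_a − nm/2| ×4
        hits = 0
        count = 0
        for combo in itertools.combinations(range(n + m), n):
            u2 = sum(ranks2[i] for i in combo) - n * (n + 1)
            count += 1
            if two_sided:
                if abs(2 * u2 - total2) >= dev_obs:
                    hits += 1
            else:
                if u2 >= u_obs2:
                    hits += 1
        p = hits / count
        return GroupComparison(
            method="mann-whitney", statistic=u_obs2 / 2.0, p_value=p,
            n_a=n, n_b=m, two_sided=two_sided, exact=True,
        )

    res = sps.mannwhitneyu(
        a, b, alternative="two-sided" if two_sided else "greater",
        method="asymptotic",
    )
    return GroupComparison(
        method="mann-whitney", statistic=float(res.statistic),
        p_value=float(res.pvalue), n_a=n, n_b=m, two_sided=two_sided, exact=False,
    )


def permutation_mean_diff(group_a: Sequence[float], group_b: Sequence[float],
                          n_perm: int = 10_000, seed: int = 0) -> GroupComparison:
    """Two-sided permutation test on the difference of means.

    p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1), so p ≥ 1/(n_perm+1)
    and is never 0; deterministic given the seed.
    """
    if n_perm < 1000:
        raise ValidationError(f"n_perm must be at least 1000, got {n_perm}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = a.size
    obs = a.mean() - b.mean()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n].mean() - perm[n:].mean()
        if abs(d) >= abs(obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return GroupComparison(
        method="permutation-welch", statistic=float(obs), p_value=float(p),
        n_a=n, n_b=b.size, two_sided=True, exact=False,
    )


# ---------------------------------------------------------------------------
# Pipeline: per-sample metrics, group comparisons, manifest
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One input sample: either a table on disk or a simulation scenario."""

    sample_id: str
    group: Optional[str] = None
    table_path: Optional[str] = None
    roi_path: Optional[str] = None
    simulate: Optional[dict] = None  # overrides for SimulationConfig


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    metrics: list[str]
    seed: int = 0
    parameters: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    metrics: pd.DataFrame  # one row per sample
    comparisons: pd.DataFrame  # one row per (metric, group pair)
    manifest: dict
    errors: list[dict]


def _params(p: dict, key: str, default):
    return p.get(key, default)


def _metric_proximity(radius):
    def f(table: CellTable, p: dict) -> float:
        res = cd138_proximity_score(table, radius)
        return float("nan") if res.score is None else float(res.score)
    return f


def _metric_density(query_text: str):
    q = PhenotypeQuery.parse(query_text)

    def f(table: CellTable, p: dict) -> float:
        return float(table.mask(q).sum()) / table.window.area_mm2
    return f


def _metric_fraction_cd138(table: CellTable, p: dict) -> float:
    n = table.n_cells
    return float(table.mask(marker("CD138")).sum()) / n if n else 0.0


def _metric_dispersion(query_text: str):
    q = PhenotypeQuery.parse(query_text)

    def f(table: CellTable, p: dict) -> float:
        return nn_distance_dispersion(table, q).sd
    return f


def _metric_max_clec9a_tcf1(table: CellTable, p: dict) -> float:
    return max_min_distance(
        table, marker("CLEC9A"), PhenotypeQuery.parse("CD3+ & TCF1+")
    )


def _metric_pooled_ei(query_text: str):
    q = PhenotypeQuery.parse(query_text)

    def f(table: CellTable, p: dict) -> float:
        clusters = delineate_clusters(
            table, marker("CD138"),
            eps=_params(p, "eps", 30.0),
            min_size=_params(p, "min_size", 10),
            alpha=_params(p, "alpha", 50.0),
        )
        if not clusters.clusters:
            return float("nan")
        rep = exclusion_index(table, clusters, q,
                              band_width=_params(p, "band_width", 50.0))
        return rep.pooled_ei
    return f


def _metric_gradient_fold(zone: int):
    def f(table: CellTable, p: dict) -> float:
        hs = detect_hotspots(
            table, marker("CLEC9A"),
            h=_params(p, "kde_bandwidth", 50.0),
            rel_threshold=_params(p, "rel_threshold", 0.25),
            min_dc=_params(p, "min_dc", 5),
        )
        if not hs.hotspots:
            return float("nan")
        part = partition_zones(table.window, hs.hotspots[0],
                               n_zones=_params(p, "n_zones", 3))
        res = zone_densities(table, part, marker("CD3"))
        return float(res.gradient["fold_change"].iloc[zone])
    return f


METRICS: dict[str, Callable[[CellTable, dict], float]] = {
    "cd138_proximity_score_r1000": _metric_proximity(CD138_RADIUS_UM),
    "cd138_proximity_score_r100": _metric_proximity(CD138_RADIUS_SMALL_UM),
    "cd138_density_mm2": _metric_density("CD138+"),
    "cd68_density_mm2": _metric_density("CD68+"),
    "cd3_density_mm2": _metric_density("CD3+"),
    "cd138_fraction": _metric_fraction_cd138,
    "nn_sd_cd3_um": _metric_dispersion("CD3+"),
    "nn_sd_cd68_um": _metric_dispersion("CD68+"),
    "max_clec9a_tcf1_um": _metric_max_clec9a_tcf1,
    "pooled_ei_cd3": _metric_pooled_ei("CD3+"),
    "pooled_ei_cd68": _metric_pooled_ei("CD68+"),
    "gradient_fold_mid": _metric_gradient_fold(1),
    "gradient_fold_distal": _metric_gradient_fold(2),
}


def _sample_seed(root_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(root_seed, spawn_key=(index,))
               .generate_state(1)[0] % (2**31))


def _build_simulation_config(spec: SampleSpec, seed: int) -> SimulationConfig:
    overrides = dict(spec.simulate or {})
    if "window" in overrides:
        w = overrides["window"]
        overrides["window"] = Window.from_bounds(*w)
    if "hotspot" in overrides and overrides["hotspot"] is not None:
        hs = overrides["hotspot"]
        overrides["hotspot"] = HotspotConfig(
            center=tuple(hs["center"]),
            n_dc=int(hs.get("n_dc", 20)),
            dc_sd=float(hs.get("dc_sd", 50.0)),
        )
    if "exclusion" in overrides and overrides["exclusion"] is not None:
        overrides["exclusion"] = ExclusionConfig(**overrides["exclusion"])
    overrides.setdefault("seed", seed)
    overrides.setdefault("sample_id", spec.sample_id)
    overrides.setdefault("group", spec.group or "synthetic")
    return SimulationConfig(**overrides)


def _load_sample(spec: SampleSpec, seed: int) -> CellTable:
    if (spec.table_path is None) == (spec.simulate is None):
        raise ConfigError(
            f"sample {spec.sample_id!r} must set exactly one of table_path/simulate"
        )
    if spec.table_path is not None:
        window = read_roi(spec.roi_path) if spec.roi_path else None
        return read_cell_table(spec.table_path, window=window,
                               sample_id=spec.sample_id, group=spec.group)
    return simulate_marrow(_build_simulation_config(spec, seed)).table


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the metric set over every sample and compare labeled groups.

    Unknown metric names fail before any computation.  A failing stage for
    one sample is logged (sample id + stage) and the remaining samples are
    still processed.  Identical config + seed yields byte-identical
    reports.
    """
    unknown = [m for m in config.metrics if m not in METRICS]
    if unknown:
        raise ConfigError(
            f"unknown metric name(s) {unknown}; available: {sorted(METRICS)}"
        )
    ids = [s.sample_id for s in config.samples]
    if len(set(ids)) != len(ids):
        raise ConfigError("sample_id values must be unique")

    errors: list[dict] = []
    rows = []
    sample_seeds = {}
    for i, spec in enumerate(config.samples):
        seed = _sample_seed(config.seed, i)
        sample_seeds[spec.sample_id] = seed
        row: dict = {"sample_id": spec.sample_id, "group": spec.group}
        try:
            table = _load_sample(spec, seed)
        except Exception as exc:  # noqa: BLE001 - reported per sample
            errors.append({"sample_id": spec.sample_id, "stage": "load",
                           "error": str(exc)})
            rows.append(row)
            continue
        for name in config.metrics:
            try:
                row[name] = METRICS[name](table, config.parameters)
            except Exception as exc:  # noqa: BLE001
                errors.append({"sample_id": spec.sample_id, "stage": name,
                               "error": str(exc)})
                row[name] = float("nan")
        rows.append(row)
    metrics_df = pd.DataFrame(rows, columns=["sample_id", "group", *config.metrics])

    comp_rows = []
    groups = sorted({s.group for s in config.samples if s.group is not None})
    for name in config.metrics:
        for ga, gb in itertools.combinations(groups, 2):
            va = metrics_df.loc[metrics_df["group"] == ga, name].dropna().to_numpy()
            vb = metrics_df.loc[metrics_df["group"] == gb, name].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                continue
            cmp_res = mann_whitney_exact(va, vb, two_sided=True)
            comp_rows.append(
                {
                    "metric": name,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": cmp_res.n_a,
                    "n_b": cmp_res.n_b,
                    "U": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "exact": cmp_res.exact,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["metric", "group_a", "group_b", "n_a", "n_b", "U", "p_value", "exact"],
    )

    manifest = {
        "package": "marrowspat",
        "version": __version__,
        "seed": config.seed,
        "sample_seeds": sample_seeds,
        "metrics": list(config.metrics),
        "parameters": dict(config.parameters),
        "samples": [
            {"sample_id": s.sample_id, "group": s.group,
             "table_path": s.table_path, "roi_path": s.roi_path,
             "simulate": s.simulate}
            for s in config.samples
        ],
    }
    return ReportBundle(metrics=metrics_df, comparisons=comparisons,
                        manifest=manifest, errors=errors)


def load_pipeline_config(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed key-value config (e.g. YAML)."""
    try:
        samples = [
            SampleSpec(
                sample_id=s["sample_id"],
                group=s.get("group"),
                table_path=s.get("table"),
                roi_path=s.get("roi"),
                simulate=s.get("simulate"),
            )
            for s in data["samples"]
        ]
        return PipelineConfig(
            samples=samples,
            metrics=list(data["metrics"]),
            seed=int(data.get("seed", 0)),
            parameters=dict(data.get("parameters", {})),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}") from exc


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write metrics.tsv, comparisons.tsv, manifest.json and errors.json.

    Output is deterministic: fixed column order, fixed float formatting,
    sorted JSON keys, no timestamps.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                          float_format="%.10g")
    bundle.comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False,
                              float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "errors.json", "w") as fh:
        json.dump(bundle.errors, fh, indent=2, sort_keys=True)
        fh.write("\n")
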