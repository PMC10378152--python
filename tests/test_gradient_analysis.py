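import numpy as np
import pytest
import shapely

from marrowspat import (
    Hotspot,
    HotspotConfig,
    PhenotypeQuery,
    SimulationConfig,
    ValidationError,
    Window,
    detect_hotspots,
    marker,
    marker_fraction_by_zone,
    partition_zones,
    simulate_marrow,
    zone_densities,
)

from conftest import make_table


W = Window.from_bounds(0, 0, 3000, 3000)


def _disc_hotspot(center=(0.0, 500.0), radius=100.0, hotspot_id=0, n_dc=10):
    return Hotspot(
        hotspot_id=hotspot_id,
        polygon=shapely.points(*center).buffer(radius),
        centroid=center,
        n_dc=n_dc,
        member_ids=[],
    )


class TestDetectHotspots:
    def test_single_gaussian_clump(self):
        rng = np.random.default_rng(0)
        dc = rng.normal((1500.0, 1500.0), 30.0, (20, 2))
        t = make_table({"CLEC9A": dc}, W)
        hs = detect_hotspots(t, marker("CLEC9A"), h=50.0)
        assert len(hs) == 1
        assert np.hypot(hs.hotspots[0].centroid[0] - dc[:, 0].mean(),
                        hs.hotspots[0].centroid[1] - dc[:, 1].mean()) < 20.0
        assert hs.hotspots[0].n_dc >= 5

    def test_two_distant_clumps(self):
        rng = np.random.default_rng(1)
        a = rng.normal((500.0, 500.0), 30.0, (20, 2))
        b = rng.normal((2500.0, 2500.0), 30.0, (20, 2))
        t = make_table({"CLEC9A": np.vstack([a, b])}, W)
        hs = detect_hotspots(t, marker("CLEC9A"), h=50.0)
        assert len(hs) == 2

    def test_no_dc_cells_empty(self):
        t = make_table({"CD3": [(0, 0)]}, W, marker_set=("CD3", "CLEC9A"))
        assert len(detect_hotspots(t, marker("CLEC9A"))) == 0

    def test_sparse_dcs_below_min_dc(self):
        # 3 isolated DCs cannot form a hotspot with min_dc=5
        t = make_table({"CLEC9A": [(100, 100), (1500, 1500), (2900, 2900)]}, W)
        assert len(detect_hotspots(t, marker("CLEC9A"), min_dc=5)) == 0

    def test_parameter_validation(self):
        t = make_table({"CLEC9A": [(0, 0)]}, W)
        with pytest.raises(ValidationError):
            detect_hotspots(t, marker("CLEC9A"), h=0.0)
        with pytest.raises(ValidationError):
            detect_hotspots(t, marker("CLEC9A"), rel_threshold=1.5)


class TestPartitionZones:
    def test_three_vertical_bands(self):
        w = Window.from_bounds(0, 0, 1000, 1000)
        hs = _disc_hotspot(center=(0.0, 500.0), radius=100.0)
        part = partition_zones(w, hs, n_zones=3, axis=(1.0, 0.0))
        assert part.axis == pytest.approx((1.0, 0.0))
        widths = np.diff(part.gradient_edges)
        assert np.allclose(widths, widths[0])
        # equal areas up to the hotspot cut-out (which hits the first band)
        assert part.gradient_areas_mm2[1] == pytest.approx(1 / 3, rel=1e-6)
        assert part.gradient_areas_mm2[2] == pytest.approx(1 / 3, rel=1e-6)
        assert part.gradient_areas_mm2[0] < 1 / 3

    def test_union_is_window_minus_hotspot(self):
        w = Window.from_bounds(0, 0, 1000, 1000)
        hs = _disc_hotspot(center=(0.0, 500.0))
        part = partition_zones(w, hs, axis=(1.0, 0.0))
        for zones in (part.gradient_zones, part.cross_zones):
            union = shapely.unary_union(zones)
            expect = w.polygon.difference(hs.polygon)
            assert union.symmetric_difference(expect).area / expect.area < 1e-3
            # pairwise disjoint (shared edges only)
            for i in range(3):
                for j in range(i + 1, 3):
                    assert zones[i].intersection(zones[j]).area < 1e-6

    def test_default_axis_points_at_window_centroid(self):
        w = Window.from_bounds(0, 0, 1000, 1000)
        hs = _disc_hotspot(center=(100.0, 500.0))
        part = partition_zones(w, hs)
        assert part.axis == pytest.approx((1.0, 0.0))

    def test_degenerate_axis_needs_explicit_direction(self):
        w = Window.from_bounds(0, 0, 1000, 1000)
        hs = _disc_hotspot(center=(500.0, 500.0))
        with pytest.raises(ValidationError, match="axis"):
            partition_zones(w, hs)
        part = partition_zones(w, hs, axis=(0.0, 1.0))
        assert part.n_zones == 3

    def test_rotation_leaves_areas_unchanged(self):
        theta = np.deg2rad(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        w1 = Window.from_bounds(0, 0, 1000, 800)
        poly2 = shapely.transform(w1.polygon, lambda c: c @ R.T)
        w2 = Window(poly2)
        c1 = np.array([100.0, 400.0])
        hs1 = _disc_hotspot(center=tuple(c1))
        c2 = R @ c1
        hs2 = Hotspot(hotspot_id=0, polygon=shapely.points(*c2).buffer(100.0),
                      centroid=tuple(c2), n_dc=10, member_ids=[])
        p1 = partition_zones(w1, hs1, axis=(1.0, 0.0))
        p2 = partition_zones(w2, hs2, axis=tuple(R @ np.array([1.0, 0.0])))
        assert np.allclose(p1.gradient_areas_mm2, p2.gradient_areas_mm2, rtol=1e-6)
        assert np.allclose(p1.cross_areas_mm2, p2.cross_areas_mm2, rtol=1e-6)


class TestZoneDensities:
    @pytest.fixture
    def uniform_setup(self):
        rng = np.random.default_rng(2)
        cd3 = rng.uniform(0, 3000, (2000, 2))
        t = make_table({"CD3": cd3}, W, marker_set=("CD3", "CLEC9A"))
        hs = _disc_hotspot(center=(100.0, 1500.0))
        part = partition_zones(W, hs)
        return t, part

    def test_count_conservation(self, uniform_setup):
        t, part = uniform_setup
        res = zone_densities(t, part, marker("CD3"))
        total = int(t.mask(marker("CD3")).sum())
        assert res.gradient["count"].sum() + res.hotspot_count == total
        assert res.cross["count"].sum() + res.hotspot_count == total

    def test_uniform_pattern_is_flat(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cd3 = rng.uniform(0, 3000, (3000, 2))
            t = make_table({"CD3": cd3}, W, marker_set=("CD3", "CLEC9A"))
            part = partition_zones(W, _disc_hotspot(center=(100.0, 1500.0)))
            res = zone_densities(t, part, marker("CD3"))
            folds = np.concatenate([
                res.gradient["fold_change"].to_numpy(),
                res.cross["fold_change"].to_numpy(),
            ])
            ok += bool(np.all((folds >= 0.8) & (folds <= 1.25)))
        assert ok >= 9

    def test_proximal_fold_is_one_and_empty_zone_zero(self):
        # all cells in the proximal band
        pts = np.column_stack([np.full(50, 200.0), np.linspace(100, 2900, 50)])
        t = make_table({"CD3": pts}, W, marker_set=("CD3", "CLEC9A"))
        part = partition_zones(W, _disc_hotspot(center=(100.0, 1500.0)),
                               axis=(1.0, 0.0))
        res = zone_densities(t, part, marker("CD3"))
        assert res.gradient["fold_change"].iloc[0] == pytest.approx(1.0)
        assert res.gradient["count"].iloc[2] == 0
        assert res.gradient["fold_change"].iloc[2] == 0.0

    def test_zero_proximal_density_flags_undefined(self):
        pts = np.column_stack([np.full(20, 2900.0), np.linspace(100, 2900, 20)])
        t = make_table({"CD3": pts}, W, marker_set=("CD3", "CLEC9A"))
        part = partition_zones(W, _disc_hotspot(center=(100.0, 1500.0)),
                               axis=(1.0, 0.0))
        res = zone_densities(t, part, marker("CD3"))
        assert res.fold_undefined
        assert np.isnan(res.gradient["fold_change"].iloc[1])

    def test_planted_gradient_recovered(self):
        cfg = SimulationConfig(
            window=Window.from_bounds(0, 0, 2000, 2000), seed=0,
            tumor_mode="diffuse", tumor_intensity=50.0, tcell_intensity=2000.0,
            hotspot=HotspotConfig(center=(200, 1000), n_dc=20, dc_sd=25),
            gradient_tau=200.0,
        )
        res = simulate_marrow(cfg)
        hs = detect_hotspots(res.table, marker("CLEC9A"), h=40.0)
        assert len(hs) == 1
        part = partition_zones(res.table.window, hs.hotspots[0])
        gr = zone_densities(res.table, part, marker("CD3"))
        g = gr.gradient["fold_change"].to_numpy()
        assert g[0] > g[1] > g[2]


class TestMarkerFractionByZone:
    def test_all_marker_positive(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 3000, (200, 2))
        # every CD3 cell is also Ki67+
        import pandas as pd
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(200)],
            "x": pts[:, 0], "y": pts[:, 1],
            "CD3": True, "Ki67": True, "CLEC9A": False,
        })
        from marrowspat import CellTable
        t = CellTable(df=df, window=W, marker_set=("CD3", "Ki67", "CLEC9A"))
        part = partition_zones(W, _disc_hotspot(center=(100.0, 1500.0)))
        frac = marker_fraction_by_zone(t, part, marker("CD3"), marker("Ki67"))
        defined = frac[~frac["undefined"]]
        assert (defined["fraction"] == 1.0).all()

    def test_empty_zone_is_undefined_not_zero(self):
        pts = [(200.0, 1500.0)]  # only the proximal band is populated
        t = make_table({"CD3": pts}, W, marker_set=("CD3", "Ki67", "CLEC9A"))
        part = partition_zones(W, _disc_hotspot(center=(100.0, 1500.0)),
                               axis=(1.0, 0.0))
        frac = marker_fraction_by_zone(t, part, marker("CD3"), marker("Ki67"))
        distal = frac[(frac["family"] == "gradient") & (frac["zone"] == 2)].iloc[0]
        assert distal["undefined"]
        assert np.isnan(distal["fraction"])

    def test_simulated_ki67_decay_is_monotone(self):
        ok = 0
        for seed in range(10):
            cfg = SimulationConfig(
                window=Window.from_bounds(0, 0, 2000, 2000), seed=seed,
                tumor_mode="diffuse", tumor_intensity=50.0, tcell_intensity=1500.0,
                hotspot=HotspotConfig(center=(200, 1000), n_dc=20, dc_sd=25),
                ki67_fraction=0.8, ki67_tau=400.0,
            )
            res = simulate_marrow(cfg)
            hs = detect_hotspots(res.table, marker("CLEC9A"), h=40.0)
            if len(hs) != 1:
                continue
            part = partition_zones(res.table.window, hs.hotspots[0])
            frac = marker_fraction_by_zone(res.table, part, marker("CD3"),
                                           marker("Ki67"))
            g = frac[frac["family"] == "gradient"]["fraction"].to_numpy()
            ok += bool(g[0] >= g[1] >= g[2])
        assert ok >= 9
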