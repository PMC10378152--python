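import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marrowspat import (
    CellTable,
    ColumnMap,
    FormatError,
    PhenotypeQuery,
    ValidationError,
    Window,
    filter_cells,
    marker,
    read_cell_table,
    read_roi,
    summarize_composition,
    write_cell_table,
    write_roi,
)

from conftest import make_table


def _write(tmp_path, text, name="cells.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCellTable:
    def test_basic_tsv(self, tmp_path):
        p = _write(tmp_path, "cell_id\tx\ty\tCD138\nc1\t0\t0\t1\nc2\t10\t0\t0\nc3\t0\t10\t1\n")
        t = read_cell_table(p)
        assert t.n_cells == 3
        assert t.marker_set == ("CD138",)
        assert int(t.mask(marker("CD138")).sum()) == 2
        assert t.df["cell_id"].tolist() == ["c1", "c2", "c3"]  # row order preserved

    def test_csv_accepted(self, tmp_path):
        p = _write(tmp_path, "cell_id,x,y,CD3\nc1,5.5,2.5,pos\nc2,1,1,neg\n", "cells.csv")
        t = read_cell_table(p)
        assert t.mask(marker("CD3")).tolist() == [True, False]

    def test_blank_coordinate_names_row(self, tmp_path):
        p = _write(tmp_path, "cell_id\tx\ty\tCD138\nc1\t0\t0\t1\nc2\t\t0\t0\nc3\t0\t10\t1\n")
        with pytest.raises(FormatError, match="row 2"):
            read_cell_table(p)

    def test_missing_coordinate_column(self, tmp_path):
        p = _write(tmp_path, "cell_id\tfoo\ty\tCD138\nc1\t0\t0\t1\n")
        with pytest.raises(FormatError, match="'x'"):
            read_cell_table(p)

    def test_duplicate_cell_id(self, tmp_path):
        p = _write(tmp_path, "cell_id\tx\ty\tCD138\nc1\t0\t0\t1\nc1\t1\t1\t0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_cell_table(p)

    def test_unrecognized_positivity_token(self, tmp_path):
        p = _write(tmp_path, "cell_id\tx\ty\tCD138\nc1\t0\t0\tmaybe\n")
        with pytest.raises(FormatError, match="maybe"):
            read_cell_table(p)

    def test_positivity_token_variants(self, tmp_path):
        p = _write(
            tmp_path,
            "cell_id\tx\ty\tM\nc1\t0\t0\tpos\nc2\t1\t0\tTRUE\nc3\t2\t0\tNeg\nc4\t3\t0\t0\n",
        )
        t = read_cell_table(p)
        assert t.mask(marker("M")).tolist() == [True, True, False, False]

    def test_column_mapping(self, tmp_path):
        p = _write(
            tmp_path,
            "Cell ID\tCell X Position\tCell Y Position\tPhenotype CD138\n"
            "c1\t10\t20\tpos\n",
        )
        t = read_cell_table(
            p,
            ColumnMap(cell_id="Cell ID", x="Cell X Position", y="Cell Y Position",
                      markers={"CD138": "Phenotype CD138"}),
        )
        assert t.marker_set == ("CD138",)
        assert t.df.loc[0, "x"] == 10.0


class TestWriteCellTable:
    def test_empty_table_header_only(self, tmp_path, unit_mm_window):
        t = make_table({"CD138": np.empty((0, 2))}, unit_mm_window)
        out = tmp_path / "empty.tsv"
        write_cell_table(t, out)
        lines = out.read_text().splitlines()
        assert lines == ["cell_id\tx\ty\tCD138"]

    def test_single_cell(self, tmp_path, unit_mm_window):
        t = make_table({"CD138": [(5.0, 7.0)]}, unit_mm_window)
        out = tmp_path / "one.tsv"
        write_cell_table(t, out)
        assert len(out.read_text().splitlines()) == 2

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        w = Window.from_bounds(0, 0, 500, 500)
        t = make_table(
            {"CD138": rng.uniform(0, 500, (20, 2)), "CD3": rng.uniform(0, 500, (15, 2))},
            w,
        )
        out = tmp_path / "rt.tsv"
        write_cell_table(t, out)
        t2 = read_cell_table(out, window=w)
        pd.testing.assert_frame_equal(t.df, t2.df)
        assert t2.marker_set == t.marker_set


@settings(derandomize=True, deadline=None, max_examples=25)
@given(
    coords=st.lists(
        st.tuples(st.floats(0, 1000, allow_nan=False), st.floats(0, 1000, allow_nan=False)),
        min_size=1, max_size=40,
    ),
    flags=st.data(),
)
def test_round_trip_property(tmp_path_factory, coords, flags):
    """read ∘ write is the identity on valid tables."""
    w = Window.from_bounds(0, 0, 1000, 1000)
    pos = flags.draw(st.lists(st.booleans(), min_size=len(coords), max_size=len(coords)))
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(coords))],
        "x": [c[0] for c in coords],
        "y": [c[1] for c in coords],
        "CD138": pos,
    })
    t = CellTable(df=df, window=w, marker_set=("CD138",))
    out = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_cell_table(t, out)
    t2 = read_cell_table(out, window=w)
    pd.testing.assert_frame_equal(t.df, t2.df)


class TestQueries:
    def test_parse_and_evaluate(self, unit_mm_window):
        t = make_table(
            {"CD3": [(0, 0), (1, 1)], "CD8": [(2, 2)]},
            unit_mm_window, marker_set=("CD3", "CD8", "GZMB"),
        )
        q = PhenotypeQuery.parse("CD3+ & !CD8+")
        assert t.mask(q).tolist() == [True, True, False]
        assert t.mask(PhenotypeQuery.parse("CD3+ | CD8+")).tolist() == [True, True, True]
        assert t.mask(PhenotypeQuery.parse("CD8-")).tolist() == [True, True, False]
        assert t.mask(PhenotypeQuery.parse("(CD3+ | CD8+) & GZMB+")).sum() == 0

    def test_unknown_marker_rejected(self, unit_mm_window):
        t = make_table({"CD3": [(0, 0)]}, unit_mm_window)
        with pytest.raises(ValidationError, match="FOXP3"):
            t.mask(PhenotypeQuery.parse("FOXP3+"))

    @pytest.mark.parametrize("bad", ["", "CD3", "CD3+ &", "(CD3+", "CD3+ CD8+"])
    def test_malformed_query(self, bad):
        with pytest.raises(ValidationError):
            PhenotypeQuery.parse(bad)


class TestFilterCells:
    def test_filter_counts(self, unit_mm_window):
        t = make_table(
            {"CD138": [(0, 0), (1, 1)], "CD3": [(2, 2), (3, 3), (4, 4)]},
            unit_mm_window,
        )
        sub = filter_cells(t, marker("CD138"))
        assert sub.n_cells == 2
        assert sub.window is t.window
        assert sub.marker_set == t.marker_set

    def test_empty_result_is_valid(self, unit_mm_window):
        t = make_table({"CD3": [(0, 0)], "CD8": [(1, 1)]}, unit_mm_window)
        sub = filter_cells(t, PhenotypeQuery.parse("CD3+ & CD8+"))
        assert sub.n_cells == 0

    def test_partition_and_idempotence(self, unit_mm_window):
        rng = np.random.default_rng(1)
        t = make_table(
            {"CD3": rng.uniform(0, 1000, (60, 2)), "CD68": rng.uniform(0, 1000, (40, 2))},
            unit_mm_window,
        )
        q = marker("CD3")
        pos, neg = filter_cells(t, q), filter_cells(t, ~q)
        assert pos.n_cells + neg.n_cells == 100
        again = filter_cells(pos, q)
        pd.testing.assert_frame_equal(again.df, pos.df)


class TestComposition:
    def test_density_fraction_and_burden_flag(self, unit_mm_window):
        t = make_table(
            {"CD138": [(i * 10, 0) for i in range(4)],
             "CD3": [(i * 10, 50) for i in range(6)]},
            unit_mm_window,
        )
        s = summarize_composition(t, [marker("CD138")])
        row = s.table.iloc[0]
        assert row["count"] == 4
        assert row["fraction"] == pytest.approx(0.40)
        assert row["density_per_mm2"] == pytest.approx(4.0)
        assert s.high_pc_burden is True  # 0.40 > 0.30 threshold

    def test_burden_flag_boundary(self, unit_mm_window):
        # exactly 30% is not "greater than 30%"
        t = make_table(
            {"CD138": [(i, 0) for i in range(3)], "CD3": [(i, 50) for i in range(7)]},
            unit_mm_window,
        )
        assert summarize_composition(t, []).high_pc_burden is False

    def test_no_match(self, unit_mm_window):
        t = make_table({"CD138": [(0, 0)]}, unit_mm_window,
                       marker_set=("CD138", "CD3"))
        s = summarize_composition(t, [marker("CD3")])
        assert s.table.iloc[0]["count"] == 0
        assert s.table.iloc[0]["density_per_mm2"] == 0

    def test_doubling_window_halves_density(self):
        pts = [(i * 10, i * 10) for i in range(10)]
        t1 = make_table({"CD3": pts}, Window.from_bounds(0, 0, 1000, 1000))
        t2 = make_table({"CD3": pts}, Window.from_bounds(0, 0, 2000, 1000))
        d1 = summarize_composition(t1, [marker("CD3")]).table.iloc[0]["density_per_mm2"]
        d2 = summarize_composition(t2, [marker("CD3")]).table.iloc[0]["density_per_mm2"]
        assert d2 == pytest.approx(d1 / 2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, (30, 2))
        w = Window.from_bounds(0, 0, 1000, 1000)
        t1 = make_table({"CD3": pts}, w)
        t2 = make_table({"CD3": pts + [500.0, -200.0]}, w.translate(500, -200))
        d1 = summarize_composition(t1, [marker("CD3")]).table["density_per_mm2"]
        d2 = summarize_composition(t2, [marker("CD3")]).table["density_per_mm2"]
        assert np.allclose(d1, d2)


class TestWindow:
    def test_boundary_is_inside(self):
        w = Window.from_bounds(0, 0, 100, 100)
        assert w.contains(0, 0)
        assert w.contains(100, 50)
        assert not w.contains(100.001, 50)

    def test_default_window_is_tight_bbox(self):
        t = make_table({"CD3": [(10, 20), (110, 220)]},
                       window=Window.from_points(np.array([10, 110]), np.array([20, 220])))
        assert t.window.bounds == (10, 20, 110, 220)

    def test_cells_outside_window_rejected(self):
        w = Window.from_bounds(0, 0, 10, 10)
        with pytest.raises(ValidationError, match="outside"):
            make_table({"CD3": [(50, 50)]}, w)

    def test_roi_round_trip(self, tmp_path):
        w = Window.from_bounds(5, 5, 205, 105)
        p = tmp_path / "roi.geojson"
        write_roi(w, p)
        w2 = read_roi(p)
        assert w2.polygon.equals(w.polygon)
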