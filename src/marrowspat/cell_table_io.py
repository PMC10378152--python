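"""Per-cell phenotype coordinate tables and regions of interest.

Multiplex-IF phenotyping software (inForm, HALO and their report add-ons)
exports one delimited text row per segmented cell, carrying the cell's X/Y
position and a boolean positivity call per stained marker.  This module
reads, validates, filters and writes such tables, and computes the basic
composition summaries (counts, fractions, densities) that every downstream
spatial statistic builds on.

Conventions
-----------
* Coordinates are micrometres (μm), continuous, with an arbitrary origin.
  Converting from pixel units is the caller's responsibility.
* The analysis region (:class:`Window`) is a simple polygon in μm.  When no
  ROI is supplied the tight axis-aligned bounding box of the cells is used.
  The window is a closed set: cells on the boundary count as inside.
* Densities are reported in cells/mm².
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "CellTableError",
    "FormatError",
    "ValidationError",
    "Window",
    "CellRecord",
    "CellTable",
    "PhenotypeQuery",
    "marker",
    "ColumnMap",
    "read_cell_table",
    "write_cell_table",
    "read_roi",
    "write_roi",
    "filter_cells",
    "CompositionSummary",
    "summarize_composition",
    "PC_BURDEN_THRESHOLD",
    "PC_BURDEN_MARKER",
]

#: Plasma-cell burden threshold: a sample whose CD138+ fraction exceeds this
#: is flagged as high-PC-burden (PC infiltration > 30%).
PC_BURDEN_THRESHOLD = 0.30
PC_BURDEN_MARKER = "CD138"

#: Fixed positivity-normalization table (case-insensitive).  Unrecognized
#: tokens are errors, never silently negative.
_POSITIVE_TOKENS = frozenset({"1", "true", "pos", "positive", "yes", "+"})
_NEGATIVE_TOKENS = frozenset({"0", "false", "neg", "negative", "no", "-", ""})

_RESERVED_COLUMNS = frozenset({"cell_id", "x", "y", "tissue_category"})


class CellTableError(ValueError):
    """Base class for cell-table errors."""


class FormatError(CellTableError):
    """The file structure (columns, delimiter) does not match expectations."""


class ValidationError(CellTableError):
    """The parsed content violates a table invariant."""


# ---------------------------------------------------------------------------
# Window
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Analysis region: a simple polygon in μm with positive area.

    Containment is closed — :meth:`contains` is true for boundary points.
    """

    polygon: Polygon

    def __post_init__(self) -> None:
        poly = self.polygon
        if not isinstance(poly, Polygon):
            raise ValidationError(f"window must be a polygon, got {type(poly).__name__}")
        if not poly.is_valid or not poly.is_simple:
            raise ValidationError("window polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValidationError("window polygon must have positive area")

    @classmethod
    def from_bounds(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "Window":
        return cls(box(float(xmin), float(ymin), float(xmax), float(ymax)))

    @classmethod
    def from_points(cls, x: np.ndarray, y: np.ndarray) -> "Window":
        """Tight axis-aligned bounding box of the given coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0:
            raise ValidationError(
                "cannot derive a bounding-box window from an empty table; "
                "supply a window explicitly"
            )
        xmin, xmax = float(x.min()), float(x.max())
        ymin, ymax = float(y.min()), float(y.max())
        # a degenerate (collinear) cloud still needs positive area
        if xmax - xmin <= 0:
            xmin, xmax = xmin - 0.5, xmax + 0.5
        if ymax - ymin <= 0:
            ymin, ymax = ymin - 0.5, ymax + 0.5
        return cls.from_bounds(xmin, ymin, xmax, ymax)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    def contains(self, x: float, y: float) -> bool:
        """Closed containment test (boundary points are inside)."""
        return bool(shapely.covers(self.polygon, shapely.points(x, y)))

    def covers_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized closed containment test."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.polygon, pts)

    def translate(self, dx: float, dy: float) -> "Window":
        return Window(shapely.affinity.translate(self.polygon, dx, dy))


# shapely.affinity is a submodule; import it once for Window.translate
import shapely.affinity  # noqa: E402


# ---------------------------------------------------------------------------
# Phenotype queries
# ---------------------------------------------------------------------------


class PhenotypeQuery:
    """Boolean combination of marker-positivity literals.

    Build programmatically (``marker("CD3") & ~marker("CD8")``) or parse from
    the compact text form used on the command line::

        CD3+ & CD8+ & GZMB+
        CD3+ & !CD8+         (CD8- is accepted as shorthand for !CD8+)
        CD138+ | CD68+

    ``&`` binds tighter than ``|``; ``!`` (or ``~``) negates; parentheses
    group.
    """

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def markers(self) -> frozenset[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def __and__(self, other: "PhenotypeQuery") -> "PhenotypeQuery":
        return _And(self, other)

    def __or__(self, other: "PhenotypeQuery") -> "PhenotypeQuery":
        return _Or(self, other)

    def __invert__(self) -> "PhenotypeQuery":
        return _Not(self)

    def validate(self, marker_set: Sequence[str]) -> None:
        unknown = self.markers() - set(marker_set)
        if unknown:
            raise ValidationError(
                f"query references markers not in the table's marker set: "
                f"{sorted(unknown)} (markers: {list(marker_set)})"
            )

    @staticmethod
    def parse(text: str) -> "PhenotypeQuery":
        return _parse_query(text)


@dataclass(frozen=True)
class _Positive(PhenotypeQuery):
    name: str

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.name].to_numpy(dtype=bool)

    def markers(self) -> frozenset[str]:
        return frozenset({self.name})

    def __str__(self) -> str:
        return f"{self.name}+"


@dataclass(frozen=True)
class _Not(PhenotypeQuery):
    operand: PhenotypeQuery

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return ~self.operand.evaluate(df)

    def markers(self) -> frozenset[str]:
        return self.operand.markers()

    def __str__(self) -> str:
        return f"!{self.operand}"


@dataclass(frozen=True)
class _And(PhenotypeQuery):
    left: PhenotypeQuery
    right: PhenotypeQuery

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return self.left.evaluate(df) & self.right.evaluate(df)

    def markers(self) -> frozenset[str]:
        return self.left.markers() | self.right.markers()

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class _Or(PhenotypeQuery):
    left: PhenotypeQuery
    right: PhenotypeQuery

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return self.left.evaluate(df) | self.right.evaluate(df)

    def markers(self) -> frozenset[str]:
        return self.left.markers() | self.right.markers()

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


def marker(name: str) -> PhenotypeQuery:
    """Positivity literal for a single marker."""
    return _Positive(name)


_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z0-9_.]+)([+-])|([&|!~()]))")


def _tokenize_query(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ValidationError(f"cannot parse phenotype query at: {text[pos:]!r}")
        if m.group(1) is not None:
            tokens.append(("literal", m.group(1) + m.group(2)))
        else:
            tokens.append(("op", m.group(3)))
        pos = m.end()
    return tokens


def _parse_query(text: str) -> PhenotypeQuery:
    tokens = _tokenize_query(text)
    if not tokens:
        raise ValidationError("empty phenotype query")
    idx = 0

    def peek() -> Optional[tuple[str, str]]:
        return tokens[idx] if idx < len(tokens) else None

    def advance() -> tuple[str, str]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or() -> PhenotypeQuery:
        node = parse_and()
        while peek() == ("op", "|"):
            advance()
            node = node | parse_and()
        return node

    def parse_and() -> PhenotypeQuery:
        node = parse_factor()
        while peek() == ("op", "&"):
            advance()
            node = node & parse_factor()
        return node

    def parse_factor() -> PhenotypeQuery:
        tok = peek()
        if tok is None:
            raise ValidationError(f"unexpected end of phenotype query: {text!r}")
        kind, value = advance()
        if kind == "op" and value in ("!", "~"):
            return ~parse_factor()
        if kind == "op" and value == "(":
            node = parse_or()
            if peek() != ("op", ")"):
                raise ValidationError(f"unbalanced parentheses in query: {text!r}")
            advance()
            return node
        if kind == "literal":
            name, sign = value[:-1], value[-1]
            lit = marker(name)
            return lit if sign == "+" else ~lit
        raise ValidationError(f"unexpected token {value!r} in query: {text!r}")

    node = parse_or()
    if idx != len(tokens):
        raise ValidationError(f"trailing tokens in query: {text!r}")
    return node


# ---------------------------------------------------------------------------
# Cell records and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: position in μm plus per-marker positivity."""

    cell_id: str
    x: float
    y: float
    phenotypes: Mapping[str, bool]
    intensities: Optional[Mapping[str, float]] = None
    tissue_category: Optional[str] = None


@dataclass
class CellTable:
    """A validated per-cell table inside an analysis window.

    ``df`` holds one row per cell with columns ``cell_id`` (str), ``x``/``y``
    (float, μm), one boolean column per marker in ``marker_set``, optional
    intensity columns named ``<marker>_intensity`` and an optional
    ``tissue_category`` column.  Row order is meaningful and preserved by all
    operations.
    """

    df: pd.DataFrame
    window: Window
    marker_set: tuple[str, ...]
    sample_id: str = ""
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.marker_set = tuple(self.marker_set)
        df = self.df.reset_index(drop=True)
        required = ["cell_id", "x", "y", *self.marker_set]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"cell table missing columns: {missing}")
        df = df.copy()
        df["cell_id"] = df["cell_id"].astype(str)
        for c in ("x", "y"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        for m in self.marker_set:
            df[m] = df[m].astype(bool)
        self.df = df
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if df["cell_id"].duplicated().any():
            dups = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
            raise ValidationError(f"duplicate cell_id values: {list(dups)}")
        coords = df[["x", "y"]].to_numpy()
        if coords.size and not np.isfinite(coords).all():
            bad = df.loc[~np.isfinite(coords).all(axis=1), "cell_id"].tolist()[:5]
            raise ValidationError(f"non-finite coordinates for cells: {bad}")
        if len(df):
            inside = self.window.covers_xy(df["x"].to_numpy(), df["y"].to_numpy())
            if not inside.all():
                outside = df.loc[~inside, "cell_id"].tolist()[:5]
                raise ValidationError(
                    f"{int((~inside).sum())} cell(s) outside the window, e.g. {outside}"
                )

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def coords(self) -> np.ndarray:
        """(n, 2) array of cell positions in μm, in row order."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def mask(self, query: PhenotypeQuery) -> np.ndarray:
        """Boolean mask over rows for a phenotype query."""
        query.validate(self.marker_set)
        if len(self.df) == 0:
            return np.zeros(0, dtype=bool)
        return query.evaluate(self.df)

    def records(self) -> Iterator[CellRecord]:
        intensity_cols = {
            c[: -len("_intensity")]: c
            for c in self.df.columns
            if c.endswith("_intensity")
        }
        has_tissue = "tissue_category" in self.df.columns
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield CellRecord(
                cell_id=d["cell_id"],
                x=d["x"],
                y=d["y"],
                phenotypes={m: bool(d[m]) for m in self.marker_set},
                intensities=(
                    {m: float(d[c]) for m, c in intensity_cols.items()}
                    if intensity_cols
                    else None
                ),
                tissue_category=d["tissue_category"] if has_tissue else None,
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[CellRecord],
        marker_set: Sequence[str],
        window: Optional[Window] = None,
        sample_id: str = "",
        group: Optional[str] = None,
    ) -> "CellTable":
        rows = []
        for r in records:
            row: dict = {"cell_id": r.cell_id, "x": r.x, "y": r.y}
            for m in marker_set:
                row[m] = bool(r.phenotypes.get(m, False))
            extra = set(r.phenotypes) - set(marker_set)
            if extra:
                raise ValidationError(
                    f"cell {r.cell_id!r} carries phenotypes outside the marker set: "
                    f"{sorted(extra)}"
                )
            if r.intensities:
                for m, v in r.intensities.items():
                    row[f"{m}_intensity"] = float(v)
            if r.tissue_category is not None:
                row["tissue_category"] = r.tissue_category
            rows.append(row)
        columns = ["cell_id", "x", "y", *marker_set]
        df = pd.DataFrame(rows, columns=columns if not rows else None)
        if rows:
            df = df.reindex(columns=list(df.columns))
        if window is None:
            window = Window.from_points(df["x"].to_numpy(), df["y"].to_numpy())
        return cls(df=df, window=window, marker_set=tuple(marker_set),
                   sample_id=sample_id, group=group)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the package's canonical fields to file column names.

    ``markers`` maps marker name → column name; ``None`` means every
    non-reserved column is taken as a marker column under its own name.
    """

    cell_id: str = "cell_id"
    x: str = "x"
    y: str = "y"
    markers: Optional[Mapping[str, str]] = None
    tissue_category: Optional[str] = None
    intensities: Optional[Mapping[str, str]] = None


def _normalize_positivity(series: pd.Series, column: str) -> pd.Series:
    tokens = series.astype(str).str.strip().str.lower()
    is_pos = tokens.isin(_POSITIVE_TOKENS)
    is_neg = tokens.isin(_NEGATIVE_TOKENS)
    bad = ~(is_pos | is_neg)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(
            f"unrecognized positivity token {series.iloc[row - 1]!r} in column "
            f"{column!r} at data row {row}"
        )
    return is_pos


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cell_table(
    path: str | Path,
    format_spec: Optional[ColumnMap] = None,
    *,
    delimiter: Optional[str] = None,
    window: Optional[Window] = None,
    sample_id: Optional[str] = None,
    group: Optional[str] = None,
) -> CellTable:
    """Read a delimited per-cell table (TSV default, CSV accepted).

    Positivity strings (``pos``/``neg``, ``1``/``0``, ``true``/``false`` …)
    are normalized to booleans; unrecognized tokens raise :class:`FormatError`.
    When ``window`` is None the tight bounding box of the cells is used.
    """
    path = Path(path)
    spec = format_spec or ColumnMap()
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    for col in (spec.cell_id, spec.x, spec.y):
        if col not in raw.columns:
            raise FormatError(f"required column {col!r} not found in {path.name} "
                              f"(columns: {list(raw.columns)})")

    df = pd.DataFrame()
    df["cell_id"] = raw[spec.cell_id].astype(str)
    for canon, col in (("x", spec.x), ("y", spec.y)):
        vals = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(
                f"non-numeric {canon} coordinate {raw[col].iloc[row - 1]!r} "
                f"at data row {row}"
            )
        df[canon] = vals.astype(float)

    if spec.markers is not None:
        marker_cols = dict(spec.markers)
    else:
        reserved = {spec.cell_id, spec.x, spec.y} | _RESERVED_COLUMNS
        if spec.tissue_category:
            reserved.add(spec.tissue_category)
        if spec.intensities:
            reserved.update(spec.intensities.values())
        marker_cols = {
            c: c for c in raw.columns
            if c not in reserved and not c.endswith("_intensity")
        }
    for name, col in marker_cols.items():
        if col not in raw.columns:
            raise FormatError(f"marker column {col!r} not found in {path.name}")
        df[name] = _normalize_positivity(raw[col], col)

    if spec.intensities:
        for name, col in spec.intensities.items():
            df[f"{name}_intensity"] = pd.to_numeric(raw[col], errors="raise")
    else:
        for col in raw.columns:
            if col.endswith("_intensity"):
                df[col] = pd.to_numeric(raw[col], errors="raise")
    tissue_col = spec.tissue_category or (
        "tissue_category" if "tissue_category" in raw.columns else None
    )
    if tissue_col:
        df["tissue_category"] = raw[tissue_col].astype(str)

    marker_set = tuple(marker_cols)
    if window is None:
        if len(df) == 0:
            raise ValidationError(
                f"{path.name} has no data rows; supply a window explicitly"
            )
        window = Window.from_points(df["x"].to_numpy(), df["y"].to_numpy())
    return CellTable(
        df=df, window=window, marker_set=marker_set,
        sample_id=sample_id if sample_id is not None else path.stem,
        group=group,
    )


def write_cell_table(table: CellTable, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a table as delimited text re-readable by :func:`read_cell_table`.

    Column order is deterministic: cell_id, x, y, markers in marker-set
    order, intensity columns, tissue category.  Marker positivity is written
    as ``1``/``0``; coordinates keep full float precision (exact round trip).
    """
    out = pd.DataFrame()
    out["cell_id"] = table.df["cell_id"]
    out["x"] = table.df["x"]
    out["y"] = table.df["y"]
    for m in table.marker_set:
        out[m] = table.df[m].astype(int)
    for col in table.df.columns:
        if col.endswith("_intensity"):
            out[col] = table.df[col]
    if "tissue_category" in table.df.columns:
        out["tissue_category"] = table.df["tissue_category"]
    out.to_csv(path, sep=delimiter, index=False)


def read_roi(path: str | Path) -> Window:
    """Read an ROI polygon from GeoJSON (coordinates in μm)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]
    if gj.get("type") == "Feature":
        gj = gj["geometry"]
    geom = shape(gj)
    if not isinstance(geom, Polygon):
        raise FormatError(f"ROI must be a polygon, got {geom.geom_type}")
    return Window(geom)


def write_roi(window: Window, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(mapping(window.polygon), fh)


# ---------------------------------------------------------------------------
# Filtering and composition
# ---------------------------------------------------------------------------


def filter_cells(table: CellTable, query: PhenotypeQuery) -> CellTable:
    """Sub-table of cells satisfying the query; order and metadata preserved."""
    m = table.mask(query)
    return CellTable(
        df=table.df.loc[m].reset_index(drop=True),
        window=table.window,
        marker_set=table.marker_set,
        sample_id=table.sample_id,
        group=table.group,
    )


@dataclass
class CompositionSummary:
    """Counts, fractions of all cells, and densities for a set of queries."""

    table: pd.DataFrame  # columns: query, count, fraction, density_per_mm2
    n_cells: int
    area_mm2: float
    cd138_fraction: Optional[float]
    high_pc_burden: Optional[bool]


def summarize_composition(
    table: CellTable,
    queries: Sequence[PhenotypeQuery],
    *,
    pc_burden_threshold: float = PC_BURDEN_THRESHOLD,
) -> CompositionSummary:
    """Per-query count, fraction of all cells and density in cells/mm².

    When the table carries the CD138 marker the sample is additionally
    flagged as high-PC-burden if its CD138+ fraction exceeds the 30%
    plasma-cell infiltration threshold.
    """
    area = table.window.area_mm2
    if area <= 0:
        raise ValidationError("window area must be positive")
    n = table.n_cells
    rows = []
    for q in queries:
        count = int(table.mask(q).sum())
        rows.append(
            {
                "query": str(q),
                "count": count,
                "fraction": (count / n) if n else 0.0,
                "density_per_mm2": count / area,
            }
        )
    cd138_fraction: Optional[float] = None
    high: Optional[bool] = None
    if PC_BURDEN_MARKER in table.marker_set:
        cd138_count = int(table.mask(marker(PC_BURDEN_MARKER)).sum())
        cd138_fraction = (cd138_count / n) if n else 0.0
        high = cd138_fraction > pc_burden_threshold
    return CompositionSummary(
        table=pd.DataFrame(rows, columns=["query", "count", "fraction", "density_per_mm2"]),
        n_cells=n,
        area_mm2=area,
        cd138_fraction=cd138_fraction,
        high_pc_burden=high,
    )
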