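import numpy as np
import pandas as pd
import pytest

from marrowspat import CellTable, Window


def make_table(layers: dict[str, np.ndarray], window: Window,
               marker_set: tuple[str, ...] | None = None,
               sample_id: str = "test") -> CellTable:
    """Build a CellTable from {marker: (n, 2) coordinate array} layers.

    Each layer's cells are positive for exactly that marker.
    """
    markers = marker_set or tuple(layers)
    frames = []
    for m, pts in layers.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        df = pd.DataFrame({
            "cell_id": [f"{m}_{i}" for i in range(len(pts))],
            "x": pts[:, 0],
            "y": pts[:, 1],
        })
        for mk in markers:
            df[mk] = mk == m
        frames.append(df)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "x", "y", *markers]
    )
    return CellTable(df=df, window=window, marker_set=markers, sample_id=sample_id)


@pytest.fixture
def unit_mm_window() -> Window:
    """A 1 mm² window (1000 × 1000 μm)."""
    return Window.from_bounds(0, 0, 1000, 1000)


@pytest.fixture
def table_factory():
    return make_table
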