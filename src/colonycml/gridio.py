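"""Plain-text grid serialization.

Two dialects are supported and round-trip exactly:

* matrix text — one lattice row per line, tab-separated ``repr`` floats;
  one file per layer;
* paired-layer CSV — long format with columns ``row,col,s,a``, one file for
  both layers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import LatticeState

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_paired_csv",
    "read_paired_csv",
]


def write_matrix(grid: np.ndarray, path: str | Path) -> None:
    """Write one layer as tab-separated rows, full float precision."""
    grid = np.asarray(grid, dtype=float)
    lines = ["\t".join(repr(float(v)) for v in row) for row in grid]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path: str | Path) -> np.ndarray:
    rows = [
        [float(tok) for tok in line.split("\t")]
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line
    ]
    return np.array(rows, dtype=float)


def write_paired_csv(state: LatticeState, path: str | Path) -> None:
    """Write both layers as long-format CSV with columns row,col,s,a."""
    rows, cols = np.indices(state.shape)
    df = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "s": state.s.ravel(),
            "a": state.a.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_paired_csv(path: str | Path, boundary: str = "periodic") -> LatticeState:
    df = pd.read_csv(path, float_precision="round_trip")
    shape = (int(df["row"].max()) + 1, int(df["col"].max()) + 1)
    s = np.zeros(shape)
    a = np.zeros(shape)
    s[df["row"], df["col"]] = df["s"]
    a[df["row"], df["col"]] = df["a"]
    return LatticeState(s, a, boundary)
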