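"""Readers for deposited per-cell proportion tables.

The study's supplementary proportion table ships as an XLSX with one row
per cell and per-method proportion columns; :func:`read_s1_data` sniffs the
header, maps columns to the canonical long-form CellCoverTable, and
validates sums-to-one.  Because the deposited file does not carry the
per-cell sample size n, n defaults to the design values (142 transect
points; pixel counts require the GSD and are left to the caller).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import TABLE_COLUMNS, validate_cover_table
from .raster import NAME_TO_ID

_METHOD_ALIASES = {
    "ground": "ground",
    "ground_transects": "ground",
    "drone_transects": "drone_transects",
    "drone_transect": "drone_transects",
    "drone_pixels": "drone_pixels",
    "drone_pixel_counts": "drone_pixels",
    "drone_pixel_count": "drone_pixels",
}
_CLASS_ALIASES = {
    "barren": "barren",
    "nonshrub": "non-shrub",
    "non_shrub": "non-shrub",
    "non-shrub": "non-shrub",
    "nonshrubs": "non-shrub",
    "shrub": "shrub",
    "shrubs": "shrub",
}


def _norm(s: str) -> str:
    return re.sub(r"[^a-z]+", "_", str(s).strip().lower()).strip("_")


def read_s1_data(path: str | Path, default_n: int = 142) -> pd.DataFrame:
    """Ingest a deposited proportion table (XLSX or CSV) as a CellCoverTable.

    Expected layout: columns ``plot`` (or plot_id), ``cell`` (or cell_id),
    and one column per method x class named like ``ground_barren``,
    ``drone_transects_shrub``, ``drone_pixel_counts_non_shrub``.  Raises
    naming the expected columns when the header cannot be mapped.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    cols = {_norm(c): c for c in raw.columns}
    plot_col = next((cols[k] for k in ("plot", "plot_id") if k in cols), None)
    cell_col = next((cols[k] for k in ("cell", "cell_id") if k in cols), None)
    if cell_col is None:
        raise ValueError("unmappable header: expected a 'cell'/'cell_id' column")
    value_cols: list[tuple[str, str, str]] = []  # (raw col, method, class name)
    for norm, rawc in cols.items():
        for m_alias, method in _METHOD_ALIASES.items():
            for c_alias, cname in _CLASS_ALIASES.items():
                if norm == f"{m_alias}_{c_alias}":
                    value_cols.append((rawc, method, cname))
    found = {(m, c) for _, m, c in value_cols}
    expected = {(m, c) for m in ("ground", "drone_transects", "drone_pixels")
                for c in ("barren", "non-shrub", "shrub")}
    if found != expected:
        missing = sorted(expected - found)
        raise ValueError(f"unmappable header: missing method x class columns {missing}")
    rows = []
    for _, r in raw.iterrows():
        for rawc, method, cname in value_cols:
            rows.append(
                {
                    "plot_id": int(r[plot_col]) if plot_col else 1,
                    "cell_id": int(r[cell_col]),
                    "method": method,
                    "altitude_m": np.nan,
                    "class": NAME_TO_ID[cname],
                    "proportion": float(r[rawc]),
                    "n": default_n,
                }
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if np.any((table["proportion"] < 0) | (table["proportion"] > 1)):
        raise ValueError("proportions outside [0, 1]")
    validate_cover_table(table, tol=1e-6)
    return table
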