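"""Plain-text readers and writers for the pipeline's data artefacts.

All tables are CSV with ISO-8601 dates; day intervals are closed
``[start, end]``.  The adjacency file is an undirected edge list
(``unit_a,unit_b``); overlap weights and populations are long-format tables.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .lattice import AreaLattice
from .prep import PreparedDataset
from .rainfall import RainfallField
from .zonation import Zonation


def write_lattice(lattice: AreaLattice, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(sorted(lattice.graph.edges), columns=["unit_a", "unit_b"])
    edges.to_csv(out / "adjacency.csv", index=False)
    rows = []
    for gi, gender in enumerate(lattice.genders):
        for ci, cdate in enumerate(lattice.census_dates):
            for unit in range(lattice.n_units):
                rows.append((unit, gender, cdate.isoformat(), int(lattice.census_pops[unit, gi, ci])))
    pd.DataFrame(rows, columns=["unit", "gender", "census_date", "pop"]).to_csv(
        out / "populations.csv", index=False
    )
    w = lattice.overlap_weights.tocoo()
    pd.DataFrame(
        {"unit": w.row, "cell": [lattice.cell_ids[c] for c in w.col], "weight": w.data}
    ).to_csv(out / "overlap_weights.csv", index=False)


def read_lattice(in_dir: str | Path) -> AreaLattice:
    """Read a lattice from ``adjacency.csv`` + ``populations.csv`` (and, when
    present, ``overlap_weights.csv``; otherwise units map 1:1 to cells)."""
    d = Path(in_dir)
    edges = pd.read_csv(d / "adjacency.csv")
    pops = pd.read_csv(d / "populations.csv")
    units = sorted(set(edges["unit_a"]) | set(edges["unit_b"]) | set(pops["unit"]))
    if units != list(range(len(units))):
        raise ValueError("units must be consecutive integers starting at 0")
    n = len(units)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges.itertuples(index=False))
    genders = tuple(sorted(pops["gender"].unique()))
    cdates = tuple(
        sorted(datetime.date.fromisoformat(s) for s in pops["census_date"].unique())
    )
    arr = np.zeros((n, len(genders), len(cdates)), dtype=np.int64)
    for row in pops.itertuples(index=False):
        gi = genders.index(row.gender)
        ci = cdates.index(datetime.date.fromisoformat(row.census_date))
        arr[row.unit, gi, ci] = row.pop
    wfile = d / "overlap_weights.csv"
    if wfile.exists():
        w = pd.read_csv(wfile)
        cell_ids = sorted(w["cell"].unique())
        cidx = {c: i for i, c in enumerate(cell_ids)}
        weights = sparse.csr_matrix(
            (w["weight"], (w["unit"], [cidx[c] for c in w["cell"]])),
            shape=(n, len(cell_ids)),
        )
    else:
        cell_ids = [f"cell_{i}" for i in range(n)]
        weights = sparse.identity(n, format="csr")
    return AreaLattice(
        n_units=n, graph=graph, cell_ids=cell_ids, overlap_weights=weights,
        census_pops=arr, census_dates=cdates, genders=genders,
    )


def write_rainfall(field: RainfallField, path: str | Path) -> None:
    n_days, n_cells = field.values.shape
    df = pd.DataFrame(
        {
            "cell": np.tile(field.cell_ids, n_days),
            "date": np.repeat(field.dates.strftime("%Y-%m-%d"), n_cells),
            "mm": field.values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_rainfall(path: str | Path) -> RainfallField:
    df = pd.read_csv(path, parse_dates=["date"])
    wide = df.pivot(index="date", columns="cell", values="mm").sort_index()
    return RainfallField(
        dates=pd.DatetimeIndex(wide.index),
        cell_ids=list(wide.columns),
        values=wide.to_numpy(),
    )


def write_counts(counts: np.ndarray, windows, gender: str, path: str | Path) -> None:
    """Write per-unit, per-window counts as ``unit,gender,window_id,count``."""
    n_units, n_windows = counts.shape
    ids = [w.window_id for w in windows]
    pd.DataFrame(
        {
            "unit": np.repeat(np.arange(n_units), n_windows),
            "gender": gender,
            "window_id": np.tile(ids, n_units),
            "count": counts.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_zonation(z: Zonation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "unit": np.arange(len(z.labels)),
            "zone": z.labels,
            "target_pop": z.target_pop,
            "replicate": z.replicate,
        }
    ).to_csv(path, index=False)


def read_zonation(path: str | Path) -> Zonation:
    df = pd.read_csv(path).sort_values("unit")
    return Zonation(
        labels=df["zone"].to_numpy(),
        target_pop=int(df["target_pop"].iloc[0]),
        replicate=int(df["replicate"].iloc[0]),
    )


def write_prepared(ds: PreparedDataset, csv_path: str | Path) -> None:
    """CSV of model rows plus a JSON sidecar with the preparation metadata."""
    csv_path = Path(csv_path)
    df = ds.data.copy()
    if "gender" not in df.columns and "gender" in ds.metadata:
        df.insert(2, "gender", ds.metadata["gender"])
    df.to_csv(csv_path, index=False)
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(ds.metadata, fh, indent=2, default=str)


def read_prepared(csv_path: str | Path) -> PreparedDataset:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return PreparedDataset(data=df.drop(columns=["gender"], errors="ignore"), metadata=meta)
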