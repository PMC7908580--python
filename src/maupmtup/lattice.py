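"""Synthetic small-area geography.

The base spatial units are cells of a rectangular rook-adjacency lattice,
standing in for the smallest census output areas ("SA1"-like units).  Each
unit carries gender-stratified census populations at three census dates and
a set of area-overlap weights onto a coarser rainfall grid.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

#: Census nights used for the synthetic populations (Australian censuses).
CENSUS_DATES: tuple[datetime.date, ...] = (
    datetime.date(2006, 8, 8),
    datetime.date(2011, 8, 9),
    datetime.date(2016, 8, 9),
)

GENDERS: tuple[str, str] = ("female", "male")


@dataclass
class AreaLattice:
    """Base spatial units with adjacency, populations and grid-overlap weights.

    Parameters
    ----------
    n_units
        Number of base units, identified by integers ``0 .. n_units-1``.
    graph
        Symmetric, irreflexive adjacency over the units; must be connected.
    cell_ids
        Identifiers of the rainfall grid cells.
    overlap_weights
        Sparse ``(n_units, n_cells)`` matrix; row ``i`` holds the fraction of
        unit ``i``'s area falling in each rainfall cell.  Rows sum to 1.
    census_pops
        Integer array ``(n_units, n_genders, n_censuses)``.
    census_dates, genders
        Labels for the last two axes of ``census_pops``.
    """

    n_units: int
    graph: nx.Graph
    cell_ids: list[str]
    overlap_weights: sparse.csr_matrix
    census_pops: np.ndarray
    census_dates: tuple[datetime.date, ...] = CENSUS_DATES
    genders: tuple[str, ...] = GENDERS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() != self.n_units:
            raise ValueError("graph node count does not match n_units")
        if any(self.graph.has_edge(i, i) for i in self.graph):
            raise ValueError("adjacency must be irreflexive")
        if self.n_units > 1 and not nx.is_connected(self.graph):
            raise ValueError("lattice adjacency graph must be connected")
        w = np.asarray(self.overlap_weights.sum(axis=1)).ravel()
        if self.overlap_weights.min() < 0:
            raise ValueError("overlap weights must be non-negative")
        if not np.allclose(w, 1.0, atol=1e-9):
            raise ValueError("overlap weights must sum to 1 per unit")
        if np.any(self.census_pops < 0):
            raise ValueError("census populations must be non-negative")
        if not np.issubdtype(self.census_pops.dtype, np.integer):
            raise ValueError("census populations must be integers")

    @property
    def unit_ids(self) -> np.ndarray:
        return np.arange(self.n_units)

    def total_population(self, census: int) -> int:
        """Total population (all genders) at census index ``census``."""
        return int(self.census_pops[:, :, census].sum())

    def unit_populations(self, census: int, gender: str | None = None) -> np.ndarray:
        """Per-unit population at a census, optionally for one gender."""
        if gender is None:
            return self.census_pops[:, :, census].sum(axis=1)
        return self.census_pops[:, self.genders.index(gender), census]


def _axis_overlaps(n: int, factor: int, anchor: float) -> list[list[tuple[int, float]]]:
    """For each unit interval [i, i+1) return (cell index, overlap length)."""
    out: list[list[tuple[int, float]]] = []
    for i in range(n):
        lo, hi = float(i), float(i + 1)
        k_lo = int(np.floor((lo - anchor) / factor))
        k_hi = int(np.floor((hi - anchor) / factor - 1e-12))
        pieces = []
        for k in range(k_lo, k_hi + 1):
            c_lo, c_hi = anchor + k * factor, anchor + (k + 1) * factor
            pieces.append((k, min(hi, c_hi) - max(lo, c_lo)))
        out.append(pieces)
    return out


def gen_lattice(
    n_rows: int,
    n_cols: int,
    grid_factor: int,
    pop_range: tuple[int, int],
    seed: int,
) -> AreaLattice:
    """Generate a rook-adjacency rectangular lattice of base units.

    The rainfall grid is coarser than the unit lattice: each grid cell spans
    ``grid_factor`` x ``grid_factor`` units.  For ``grid_factor > 1`` the grid
    is offset by half a unit so that boundary units genuinely straddle cells
    and receive fractional overlap weights; for ``grid_factor == 1`` cells
    coincide with units exactly.

    Unit totals at the first census are uniform draws from ``pop_range``
    (inclusive), split between genders binomially; the second and third
    censuses perturb each unit-gender count by a uniform +/-10% drift.
    """
    for name, val in (("n_rows", n_rows), ("n_cols", n_cols), ("grid_factor", grid_factor)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if n_rows * n_cols < 4:
        raise ValueError("lattice must have at least 4 units (n_rows*n_cols >= 4)")
    lo, hi = pop_range
    if lo < 0 or hi < lo:
        raise ValueError(f"pop_range must be a non-negative interval, got {pop_range}")

    rng = np.random.default_rng(seed)
    n_units = n_rows * n_cols

    g2 = nx.grid_2d_graph(n_rows, n_cols)
    graph = nx.relabel_nodes(g2, {(r, c): r * n_cols + c for r, c in g2.nodes})

    anchor = 0.0 if grid_factor == 1 else -0.5
    row_ov = _axis_overlaps(n_rows, grid_factor, anchor)
    col_ov = _axis_overlaps(n_cols, grid_factor, anchor)

    cell_index: dict[tuple[int, int], int] = {}
    cell_ids: list[str] = []
    rows_w, cols_w, vals_w = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            unit = r * n_cols + c
            for kr, fr in row_ov[r]:
                for kc, fc in col_ov[c]:
                    key = (kr, kc)
                    if key not in cell_index:
                        cell_index[key] = len(cell_ids)
                        cell_ids.append(f"cell_{kr}_{kc}")
                    rows_w.append(unit)
                    cols_w.append(cell_index[key])
                    vals_w.append(fr * fc)  # unit area is 1
    weights = sparse.csr_matrix(
        (vals_w, (rows_w, cols_w)), shape=(n_units, len(cell_ids))
    )

    totals = rng.integers(lo, hi + 1, size=n_units)
    male1 = rng.binomial(totals, 0.5)
    pops = np.zeros((n_units, 2, 3), dtype=np.int64)
    pops[:, 0, 0] = totals - male1
    pops[:, 1, 0] = male1
    for census in (1, 2):
        drift = rng.uniform(-0.1, 0.1, size=(n_units, 2))
        prev = pops[:, :, census - 1]
        pops[:, :, census] = np.maximum(0, np.rint(prev * (1.0 + drift))).astype(np.int64)

    return AreaLattice(
        n_units=n_units,
        graph=graph,
        cell_ids=cell_ids,
        overlap_weights=weights,
        census_pops=pops,
        meta={"n_rows": n_rows, "n_cols": n_cols, "grid_factor": grid_factor},
    )
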