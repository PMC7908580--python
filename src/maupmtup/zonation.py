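"""Automated zone design: contiguous aggregation of base units to a target
population, in the AZP (automated zoning procedure) family.

The builder (1) seeds ``round(total_pop / target)`` zones at random units,
(2) grows regions by repeatedly attaching the unassigned neighbour whose
attachment least increases the squared-deviation objective
``sum_z (pop_z - target)^2``, and (3) refines by single-unit boundary moves
that preserve contiguity of the donor zone, until no improving move exists.
Ties are broken by lowest unit identifier, so a given seed is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .lattice import AreaLattice


@dataclass
class Zonation:
    """A partition of base units into contiguous zones.

    ``labels[i]`` is the zone of unit ``i`` (``-1`` marks an unassigned unit,
    which :func:`validate_zonation` reports as a completeness failure).
    ``target_pop`` 0 denotes the identity (base-unit) zonation.
    """

    labels: np.ndarray
    target_pop: int
    replicate: int = 0

    @property
    def name(self) -> str:
        if self.target_pop == 0:
            return "base"
        return f"t{self.target_pop}_r{self.replicate}"

    @property
    def zones(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    def members(self, zone: int) -> np.ndarray:
        return np.flatnonzero(self.labels == zone)


@dataclass
class ZonationReport:
    """Validity report: completeness, per-zone contiguity and populations."""

    complete: bool
    missing_units: list[int]
    contiguous: dict[int, bool]
    zone_pops: dict[int, float]
    target_pop: int

    @property
    def ok(self) -> bool:
        return self.complete and all(self.contiguous.values())

    @property
    def max_abs_deviation(self) -> float:
        if self.target_pop <= 0 or not self.zone_pops:
            return 0.0
        return max(abs(p - self.target_pop) for p in self.zone_pops.values())


def identity_zonation(lattice: AreaLattice) -> Zonation:
    """Each base unit forms its own zone (``target_pop`` recorded as 0)."""
    return Zonation(labels=np.arange(lattice.n_units), target_pop=0, replicate=0)


def validate_zonation(z: Zonation, lattice: AreaLattice) -> ZonationReport:
    """Check partition completeness and per-zone contiguity; report populations."""
    labels = np.asarray(z.labels)
    missing = np.flatnonzero(labels < 0).tolist()
    pops = lattice.unit_populations(census=len(lattice.census_dates) - 1).astype(float)
    contiguous: dict[int, bool] = {}
    zone_pops: dict[int, float] = {}
    for zone in np.unique(labels[labels >= 0]):
        members = np.flatnonzero(labels == zone)
        sub = lattice.graph.subgraph(members.tolist())
        contiguous[int(zone)] = nx.is_connected(sub) if len(members) > 1 else True
        zone_pops[int(zone)] = float(pops[members].sum())
    return ZonationReport(
        complete=not missing,
        missing_units=missing,
        contiguous=contiguous,
        zone_pops=zone_pops,
        target_pop=z.target_pop,
    )


def _objective_delta_grow(pop_z: float, pop_u: float, target: float) -> float:
    return (pop_z + pop_u - target) ** 2 - (pop_z - target) ** 2


def _removal_keeps_connected(graph: nx.Graph, members: set[int], unit: int) -> bool:
    rest = members - {unit}
    if not rest:
        return False  # zones may not be emptied
    sub = graph.subgraph(rest)
    return nx.is_connected(sub)


def build_zonation(
    lattice: AreaLattice,
    target_pop: int,
    reference_pops: np.ndarray | None = None,
    seed: int = 0,
    replicate: int = 0,
) -> Zonation:
    """Build one contiguous zonation near a target zone population.

    ``reference_pops`` defaults to the final-census total populations (the
    zonations are built once from the last census and reused everywhere).
    """
    if target_pop <= 0:
        raise ValueError(f"target_pop must be positive, got {target_pop}")
    if lattice.n_units > 1 and not nx.is_connected(lattice.graph):
        raise ValueError("lattice must be connected")
    if reference_pops is None:
        reference_pops = lattice.unit_populations(census=len(lattice.census_dates) - 1)
    pops = np.asarray(reference_pops, dtype=float)
    n = lattice.n_units
    total = pops.sum()
    k = max(1, int(round(total / target_pop)))
    if k >= n:
        z = identity_zonation(lattice)
        return Zonation(labels=z.labels, target_pop=target_pop, replicate=replicate)
    if k == 1:
        return Zonation(labels=np.zeros(n, dtype=int), target_pop=target_pop, replicate=replicate)

    rng = np.random.default_rng(seed)
    graph = lattice.graph
    labels = np.full(n, -1, dtype=int)
    seeds = rng.choice(n, size=k, replace=False)
    zone_pop = np.zeros(k)
    for zi, u in enumerate(seeds):
        labels[u] = zi
        zone_pop[zi] = pops[u]

    # region growing: attach the (zone, unassigned neighbour) pair with the
    # smallest objective increase; ties by lowest unit id, then lowest zone
    n_unassigned = n - k
    while n_unassigned:
        best = None
        for u in range(n):
            if labels[u] >= 0:
                continue
            for nb in graph.neighbors(u):
                zi = labels[nb]
                if zi < 0:
                    continue
                d = _objective_delta_grow(zone_pop[zi], pops[u], target_pop)
                cand = (d, u, zi)
                if best is None or cand < best:
                    best = cand
        if best is None:  # unreachable on a connected graph
            raise RuntimeError("region growing stalled")
        _, u, zi = best
        labels[u] = zi
        zone_pop[zi] += pops[u]
        n_unassigned -= 1

    # local search: single-unit boundary moves preserving donor contiguity
    members = {zi: set(np.flatnonzero(labels == zi).tolist()) for zi in range(k)}
    improved = True
    while improved:
        improved = False
        for u in range(n):
            src = labels[u]
            if len(members[src]) <= 1:
                continue
            targets = sorted({labels[nb] for nb in graph.neighbors(u)} - {src})
            if not targets:
                continue
            best = None
            for dst in targets:
                d = (
                    (zone_pop[src] - pops[u] - target_pop) ** 2
                    - (zone_pop[src] - target_pop) ** 2
                    + (zone_pop[dst] + pops[u] - target_pop) ** 2
                    - (zone_pop[dst] - target_pop) ** 2
                )
                if d < -1e-9 and (best is None or d < best[0]):
                    if _removal_keeps_connected(graph, members[src], u):
                        best = (d, dst)
            if best is not None:
                _, dst = best
                members[src].discard(u)
                members[dst].add(u)
                zone_pop[src] -= pops[u]
                zone_pop[dst] += pops[u]
                labels[u] = dst
                improved = True

    # compact zone ids (zones can never be emptied by the moves above)
    _, labels = np.unique(labels, return_inverse=True)
    return Zonation(labels=labels, target_pop=target_pop, replicate=replicate)


def build_zonation_set(
    lattice: AreaLattice,
    targets: tuple[int, ...] = (500, 1000, 2500, 5000, 7500),
    replicates: int = 5,
    seed: int = 0,
    reference_pops: np.ndarray | None = None,
) -> list[Zonation]:
    """The study's zonation system: the base zonation plus ``replicates``
    aggregations at each target (default 1 + 5 x 5 = 26 zonations)."""
    out = [identity_zonation(lattice)]
    for ti, target in enumerate(targets):
        for rep in range(replicates):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ti, rep))
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            out.append(
                build_zonation(
                    lattice, target, reference_pops=reference_pops,
                    seed=sub_seed, replicate=rep,
                )
            )
    return out
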