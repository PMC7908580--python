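import itertools

import networkx as nx
import numpy as np
import pytest

import maupmtup as m


def _all_contiguous_partitions(graph, n_parts):
    """Brute-force oracle: every partition of the nodes into n_parts
    non-empty connected blocks."""
    nodes = sorted(graph.nodes)
    for labels in itertools.product(range(n_parts), repeat=len(nodes)):
        if len(set(labels)) != n_parts:
            continue
        blocks = {}
        for node, lab in zip(nodes, labels):
            blocks.setdefault(lab, set()).add(node)
        if all(nx.is_connected(graph.subgraph(b)) for b in blocks.values()):
            yield blocks


def _objective(blocks, pops, target):
    return sum((sum(pops[u] for u in b) - target) ** 2 for b in blocks.values())


class TestBuildZonation:
    def test_four_path_recovers_unique_optimum(self, path4_lattice):
        pops = np.array([250.0, 250.0, 250.0, 250.0])
        # oracle: the unique objective-optimal contiguous 2-partition
        best = min(
            _all_contiguous_partitions(path4_lattice.graph, 2),
            key=lambda b: _objective(b, pops, 500),
        )
        assert sorted(map(sorted, best.values())) == [[0, 1], [2, 3]]
        for seed in range(5):
            z = m.build_zonation(path4_lattice, 500, reference_pops=pops, seed=seed)
            groups = sorted(sorted(z.members(zz).tolist()) for zz in z.zones)
            assert groups == [[0, 1], [2, 3]]

    def test_degenerate_target_single_zone(self, small_lattice):
        total = int(small_lattice.unit_populations(2).sum())
        z = m.build_zonation(small_lattice, 10 * total, seed=0)
        assert z.n_zones == 1

    def test_study_configuration_yields_26_zonations(self):
        lat = m.gen_lattice(12, 12, 2, (150, 450), seed=3)
        zs = m.build_zonation_set(lat, targets=(500, 1000, 2500, 5000, 7500),
                                  replicates=5, seed=1)
        assert len(zs) == 26
        assert zs[0].target_pop == 0  # base zonation first
        for z in zs:
            assert m.validate_zonation(z, lat).ok

    def test_population_conservation(self, small_lattice):
        pops = small_lattice.unit_populations(2).astype(float)
        z = m.build_zonation(small_lattice, 800, seed=4)
        rep = m.validate_zonation(z, small_lattice)
        assert sum(rep.zone_pops.values()) == pops.sum()

    def test_boundary_move_local_optimality(self, small_lattice):
        """After convergence no single contiguity-preserving boundary move
        may reduce the squared-deviation objective."""
        pops = small_lattice.unit_populations(2).astype(float)
        target = 900
        z = m.build_zonation(small_lattice, target, seed=6)
        labels = z.labels.copy()
        zone_pop = {zz: pops[z.members(zz)].sum() for zz in z.zones}
        g = small_lattice.graph
        for u in range(small_lattice.n_units):
            src = labels[u]
            members = set(np.flatnonzero(labels == src).tolist())
            if len(members) <= 1:
                continue
            if not nx.is_connected(g.subgraph(members - {u})):
                continue
            for dst in {labels[nb] for nb in g.neighbors(u)} - {src}:
                delta = (
                    (zone_pop[src] - pops[u] - target) ** 2
                    - (zone_pop[src] - target) ** 2
                    + (zone_pop[dst] + pops[u] - target) ** 2
                    - (zone_pop[dst] - target) ** 2
                )
                assert delta >= -1e-6

    def test_replicates_differ(self):
        lat = m.gen_lattice(5, 5, 1, (100, 300), seed=8)
        zs = [m.build_zonation(lat, 1200, seed=s) for s in range(5)]
        assert any(
            not np.array_equal(a.labels, b.labels)
            for a, b in itertools.combinations(zs, 2)
        )

    def test_invalid_target_rejected(self, small_lattice):
        with pytest.raises(ValueError, match="positive"):
            m.build_zonation(small_lattice, 0)


class TestIdentityZonation:
    def test_each_unit_its_own_zone(self, small_lattice):
        z = m.identity_zonation(small_lattice)
        assert z.n_zones == small_lattice.n_units
        assert z.target_pop == 0
        assert m.validate_zonation(z, small_lattice).ok

    def test_identity_aggregation_preserves_data(self, small_lattice):
        import datetime as dt
        windows = m.window_instances(
            dt.date(2010, 1, 1), dt.date(2012, 12, 31), m.WindowArrangement(12, 3, 0)
        )
        n, w = small_lattice.n_units, len(windows)
        rng = np.random.default_rng(0)
        events = rng.poisson(3.0, (n, w))
        pops = rng.uniform(50, 100, (n, w))
        import pandas as pd
        dates = pd.date_range("2009-06-01", "2013-01-31", freq="D")
        daily = rng.uniform(0, 2, (len(dates), n))
        z = m.identity_zonation(small_lattice)
        ds = m.aggregate_by_zonation(z, events, pops, daily, dates, windows)
        got = ds.data.pivot(index="zone", columns="window_id", values="y").to_numpy()
        assert np.array_equal(got, events)


class TestValidateZonation:
    def test_missing_unit_flagged(self, small_lattice):
        labels = np.arange(small_lattice.n_units)
        labels[3] = -1
        rep = m.validate_zonation(m.Zonation(labels, target_pop=0), small_lattice)
        assert not rep.complete and rep.missing_units == [3]
        assert not rep.ok

    def test_non_contiguous_zone_flagged(self, small_lattice):
        labels = np.arange(small_lattice.n_units)
        labels[35] = labels[0]  # units 0 and 35 are opposite corners
        rep = m.validate_zonation(m.Zonation(labels, target_pop=0), small_lattice)
        assert rep.complete
        assert rep.contiguous[int(labels[0])] is False
        assert not rep.ok
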