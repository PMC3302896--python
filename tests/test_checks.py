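import networkx as nx
import numpy as np
import pytest

from betatopo.checks import (
    find_cycles,
    incompatibility_graph,
    is_two_colorable,
    nonlocal_enabling_pairs,
    resolved_neighbors,
    two_color,
    validate_topology,
)
from betatopo.datamodel import ModelConfig, Orientation

from util_build import build_contact, build_protein, topology

A = Orientation.ANTIPARALLEL
P = Orientation.PARALLEL


class TestCycles:
    def test_triangle_found(self):
        p = build_protein([6, 6, 6])
        t = topology(
            build_contact(p, 1, 2), build_contact(p, 2, 3), build_contact(p, 1, 3)
        )
        cycles = find_cycles(t, 3)
        assert len(cycles) == 1
        assert sorted(cycles[0]) == [1, 2, 3]

    def test_path_is_acyclic(self):
        p = build_protein([6, 6, 6, 6])
        t = topology(
            build_contact(p, 1, 2), build_contact(p, 2, 3), build_contact(p, 3, 4)
        )
        assert find_cycles(t, 4) == []

    def test_agrees_with_forest_check_on_random_graphs(self):
        rng = np.random.default_rng(17)
        p = build_protein([6] * 8)
        for _ in range(200):
            edges = set()
            for _ in range(rng.integers(0, 9)):
                i, j = sorted(rng.choice(8, size=2, replace=False) + 1)
                edges.add((int(i), int(j)))
            t = topology(*(build_contact(p, i, j) for i, j in edges))
            g = nx.Graph(list(edges))
            has_cycle = not nx.is_forest(g) if g.number_of_edges() else False
            assert bool(find_cycles(t, 8)) == has_cycle


class TestTwoColor:
    def test_single_contact_colorable(self):
        p = build_protein([6, 6, 6])
        ok, coloring = is_two_colorable(topology(build_contact(p, 1, 2)))
        assert ok and set(coloring.values()) <= {0, 1}

    def test_three_mutually_incompatible_contacts(self):
        # three partners all overlapping on one long central strand
        p = build_protein([4, 12, 4, 4, 4], pid="star")
        # star around strand 2: all three registers cover its low end
        t = topology(
            build_contact(p, 1, 2, A, offset=-8),
            build_contact(p, 2, 3, A, offset=0),
            build_contact(p, 2, 4, A, offset=1),
        )
        g = incompatibility_graph(t)
        assert g.number_of_edges() == 3  # pairwise incompatible
        ok, witness = is_two_colorable(t)
        assert not ok
        assert len(witness) == 3

    def test_witness_is_genuine_odd_cycle(self):
        g = nx.cycle_graph(5)
        ok, witness = two_color(g)
        assert not ok
        assert len(witness) % 2 == 1
        for u, v in zip(witness, witness[1:] + witness[:1]):
            assert g.has_edge(u, v)

    def test_property_agrees_with_exhaustive_coloring(self):
        rng = np.random.default_rng(5)
        from itertools import product

        for _ in range(300):
            n = int(rng.integers(1, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            ok, _w = two_color(g)
            brute = any(
                all(c[u] != c[v] for u, v in g.edges)
                for c in (dict(zip(g.nodes, bits)) for bits in product([0, 1], repeat=n))
            )
            assert ok == brute

    def test_invariant_under_contact_relabeling(self, fx5):
        t = fx5.planted
        ok1, _ = is_two_colorable(t)
        reordered = type(t)(contacts=tuple(reversed(t.contacts)), objective=t.objective)
        ok2, _ = is_two_colorable(reordered)
        assert ok1 == ok2


class TestNeighborResolution:
    def test_circular_wrap(self):
        p = build_protein([6, 6, 6, 6])
        cfg = ModelConfig()
        assert resolved_neighbors(p, 1, cfg) == (4, 2)
        assert resolved_neighbors(p, 4, cfg) == (3, 1)

    def test_small_strands_skipped(self):
        p = build_protein([6, 2, 6, 6])
        cfg = ModelConfig()
        # strand 2 is too short to be a neighbor: 1's next neighbor resolves to 3
        assert resolved_neighbors(p, 1, cfg) == (4, 3)

    def test_threshold_separation_adds_bridging_pairs(self):
        p = build_protein([6, 6, 6, 6, 6])
        cfg = ModelConfig()
        pairs = nonlocal_enabling_pairs(p, 1, 4, cfg)
        assert {(1, 3), (2, 4)} <= pairs
        assert (1, 4) not in pairs


class TestValidateTopology:
    """Hand-built violations must each trip exactly the intended check."""

    def test_planted_fixture_passes_everything(self, fx4, fx5):
        for fx in (fx4, fx5):
            report = validate_topology(fx.planted, fx.protein)
            assert report.ok, report.failed()

    def test_pretzel_quartet(self):
        # crossing chain (1,3),(1,4),(2,4) in one sheet; (1,4) kept local by
        # a raised threshold so only the pretzel rule is at stake
        cfg = ModelConfig(nonlocal_threshold=4, hbond_tolerance=0.9)
        p = build_protein([6, 6, 6, 6, 6])
        t = topology(
            build_contact(p, 1, 3, A, offset=0),
            build_contact(p, 1, 4, A, offset=4),   # covers strand-4 high end
            build_contact(p, 2, 4, A, offset=-2),  # covers strand-4 low end
            build_contact(p, 4, 5, A, offset=0),
        )
        report = validate_topology(t, p, cfg)
        assert report.failed() == ["pretzel"], report.to_dict()

    def test_barrel_triangle(self):
        # 1-2-3 triangle with disjoint same-orientation registers: the cycle
        # check alone must reject it
        cfg = ModelConfig(hbond_tolerance=0.9)
        p = build_protein([6, 6, 6, 4, 4])
        t = topology(
            build_contact(p, 1, 2, P, offset=3),
            build_contact(p, 2, 3, P, offset=3),
            build_contact(p, 1, 3, P, offset=-3),
            build_contact(p, 4, 5, P, offset=0),
        )
        report = validate_topology(t, p, cfg)
        assert report.failed() == ["acyclic"], report.to_dict()

    def test_zero_contact_strand(self):
        # a strand with no contact violates the contact requirement (and,
        # as a consequence, its residue budget — nothing else)
        cfg = ModelConfig(hbond_tolerance=0.9)
        p = build_protein([6, 6, 6, 6])
        t = topology(build_contact(p, 1, 2, A), build_contact(p, 2, 3, A))
        report = validate_topology(t, p, cfg)
        assert "degree_bounds" in report.failed()
        assert set(report.failed()) <= {"degree_bounds", "residue_budget"}
        assert report.checks["degree_bounds"].witnesses == [(4, 0)]

    def test_both_orientation_pair(self):
        cfg = ModelConfig(hbond_tolerance=0.9)
        p = build_protein([6, 6, 4, 6, 6, 4])
        t = topology(
            build_contact(p, 1, 2, A, offset=0),
            build_contact(p, 1, 2, P, offset=0),
            build_contact(p, 3, 4, A, offset=0),
            build_contact(p, 4, 5, A, offset=0),
            build_contact(p, 5, 6, A, offset=0),
        )
        report = validate_topology(t, p, cfg)
        assert report.failed() == ["orientation_exclusive"], report.to_dict()
        assert report.checks["orientation_exclusive"].witnesses == [(1, 2)]

    def test_hbond_budget_breach(self):
        # minimal registers on short strands undershoot 0.638*N_beta by
        # more than 15%
        cfg = ModelConfig()
        p = build_protein([4, 4, 4, 4])
        t = topology(
            build_contact(p, 1, 2, A, offset=2),
            build_contact(p, 2, 3, A, offset=2),
            build_contact(p, 3, 4, A, offset=2),
        )
        report = validate_topology(t, p, cfg)
        assert report.failed() == ["hbond_budget"], report.to_dict()

    def test_lone_nonlocal_contact_fails_interlock(self):
        cfg = ModelConfig(hbond_tolerance=0.9)
        p = build_protein([6, 6, 6, 6, 6])
        t = topology(
            build_contact(p, 1, 4, A, offset=0),
            build_contact(p, 2, 3, A, offset=0),
            build_contact(p, 3, 4, A, offset=0),
            build_contact(p, 4, 5, A, offset=0),
        )
        report = validate_topology(t, p, cfg)
        assert "interlock" in report.failed()
        assert (1, 4) in report.checks["interlock"].witnesses
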