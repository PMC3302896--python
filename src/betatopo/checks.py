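"""Graph-theoretic validation of predicted sheet topologies.

Every constraint family of the optimization model is re-checked here,
outside the solver: contact cardinalities, residue budgets, face-overlap
exclusion, edge/neighbor rules for 3-contact strands, non-local enabling,
pretzel and interlock rules, terminal-strand sets, the hydrogen-bond
budget, acyclicity of the contact graph (barrel elimination) and
two-colorability of the contact-incompatibility graph.  The brute-force
enumeration oracle filters candidate topologies through exactly this code
path, which is what makes it a meaningful cross-check of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .datamodel import (
    ModelConfig,
    Orientation,
    ProteinRecord,
    SheetTopology,
    StrandContact,
)

__all__ = [
    "contact_graph",
    "find_cycles",
    "incompatibility_graph",
    "two_color",
    "is_two_colorable",
    "resolved_neighbors",
    "nonlocal_enabling_pairs",
    "CheckResult",
    "ValidationReport",
    "validate_topology",
]


def contact_graph(topology: SheetTopology, n_strands: int | None = None) -> nx.Graph:
    g = nx.Graph()
    if n_strands:
        g.add_nodes_from(range(1, n_strands + 1))
    g.add_edges_from(c.pair for c in topology.contacts)
    return g


def find_cycles(topology: SheetTopology, n_strands: int | None = None) -> list[list[int]]:
    """All simple cycles (length ≥ 3) of the strand-contact graph.

    A non-empty result marks a (sub-)barrel arrangement, which the model
    excludes.
    """
    g = contact_graph(topology, n_strands)
    return [list(c) for c in nx.simple_cycles(g)]


def _intervals_overlap(a: tuple[int, int] | None, b: tuple[int, int] | None) -> bool:
    if a is None or b is None:
        return False
    return min(a[1], b[1]) - max(a[0], b[0]) + 1 >= 1


def incompatibility_graph(topology: SheetTopology) -> nx.Graph:
    """Contacts as nodes; edges join contacts forced onto opposite faces.

    Two contacts sharing a strand are incompatible (must take opposite faces
    of the shared strand) when they have opposing orientations or their
    aligned residue intervals on the shared strand overlap in at least one
    position.
    """
    g = nx.Graph()
    contacts = topology.contacts
    g.add_nodes_from(range(len(contacts)))
    for a, b in combinations(range(len(contacts)), 2):
        ca, cb = contacts[a], contacts[b]
        shared = set(ca.pair) & set(cb.pair)
        if not shared:
            continue
        opposing = ca.orientation is not cb.orientation
        sharing = any(
            _intervals_overlap(ca.interval_on(s), cb.interval_on(s)) for s in shared
        )
        if opposing or sharing:
            g.add_edge(a, b)
    return g


def two_color(graph: nx.Graph) -> tuple[bool, dict | list]:
    """Breadth-first 2-coloring.

    Returns (True, coloring) with colors in {0, 1}, or (False, odd-cycle
    witness) as a node list when the graph is not bipartite.
    """
    color: dict = {}
    parent: dict = {}
    for root in graph.nodes:
        if root in color:
            continue
        color[root] = 0
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in graph.neighbors(u):
                if v not in color:
                    color[v] = 1 - color[u]
                    parent[v] = u
                    queue.append(v)
                elif color[v] == color[u]:
                    # walk both BFS-tree paths to the root, splice at the
                    # lowest common ancestor -> odd cycle
                    pu, pv = [u], [v]
                    while pu[-1] is not None:
                        pu.append(parent[pu[-1]])
                    while pv[-1] is not None:
                        pv.append(parent[pv[-1]])
                    pu, pv = pu[:-1], pv[:-1]
                    common = set(pu) & set(pv)
                    iu = next(i for i, n in enumerate(pu) if n in common)
                    iv = next(i for i, n in enumerate(pv) if n in common)
                    witness = pu[: iu + 1] + pv[:iv][::-1]
                    return False, witness
    return True, color


def is_two_colorable(topology: SheetTopology) -> tuple[bool, dict | list]:
    """Bipartiteness of the contact-incompatibility graph.

    True means a consistent assignment of every contact to one of the two
    faces of each shared strand exists.
    """
    return two_color(incompatibility_graph(topology))


# -- neighbor resolution ---------------------------------------------------


def resolved_neighbors(
    protein: ProteinRecord, i: int, config: ModelConfig
) -> tuple[int, int]:
    """Circular sequence neighbors of strand i, skipping very small strands.

    The strand preceding the first strand is the last one and vice versa.
    Strands shorter than ``min_neighbor_length`` are stepped over (a small
    strand cannot pull sequentially distant parts of the chain together);
    if no strand qualifies, the immediate circular neighbor is used.
    """
    n = protein.n_strands

    def walk(start: int, step: int) -> int:
        cur = start
        for _ in range(n - 1):
            cur = (cur - 1 + step) % n + 1
            if cur == i:
                break
            if protein.strand(cur).length >= config.min_neighbor_length:
                return cur
        return (start - 1 + step) % n + 1  # fallback: immediate neighbor

    return walk(i, -1), walk(i, +1)


def nonlocal_enabling_pairs(
    protein: ProteinRecord, i: int, j: int, config: ModelConfig
) -> set[tuple[int, int]]:
    """Strand pairs whose contact enables the non-local contact (i, j).

    These are the contacts of i and j with their resolved neighbors; when
    the separation equals the non-local threshold exactly, the two bridging
    contacts (i, j−1) and (i+1, j) are added as well.
    """
    out: set[tuple[int, int]] = set()
    for s in (i, j):
        for nb in resolved_neighbors(protein, s, config):
            if nb != s:
                out.add((min(s, nb), max(s, nb)))
    if j - i == config.nonlocal_threshold:
        if j - 1 > i:
            out.add((i, j - 1))
        if i + 1 < j:
            out.add((i + 1, j))
    out.discard((i, j))
    return out


# -- full validation -------------------------------------------------------


@dataclass
class CheckResult:
    passed: bool
    witnesses: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"passed": self.passed, "witnesses": self.witnesses}


@dataclass
class ValidationReport:
    checks: dict[str, CheckResult]
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def failed(self) -> list[str]:
        return [name for name, c in self.checks.items() if not c.passed]

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "checks": {k: v.to_dict() for k, v in self.checks.items()},
            "warnings": self.warnings,
        }


def _terminal_sorted(protein: ProteinRecord, config: ModelConfig) -> list[int]:
    """Strand indices sorted by (length, hydrophobic count) ascending."""
    return sorted(
        (s.index for s in protein.strands),
        key=lambda idx: (
            protein.strand(idx).length,
            protein.strand(idx).hydrophobic_count(config.hydrophobic_set),
            idx,
        ),
    )


def validate_topology(
    topology: SheetTopology,
    protein: ProteinRecord,
    config: ModelConfig | None = None,
) -> ValidationReport:
    """Re-check every constraint family on a complete topology."""
    config = config or ModelConfig()
    n = protein.n_strands
    contacts = topology.contacts
    checks: dict[str, CheckResult] = {}
    warnings: list = []

    # one orientation per pair
    seen: dict[tuple[int, int], set] = {}
    for c in contacts:
        seen.setdefault(c.pair, set()).add(c.orientation)
    dup = [p for p, os in seen.items() if len(os) > 1]
    checks["orientation_exclusive"] = CheckResult(not dup, dup)

    # total contacts <= N - 1
    total = len(contacts)
    checks["total_contacts"] = CheckResult(
        total <= n - 1, [] if total <= n - 1 else [total]
    )

    # 1 <= degree <= max_contacts_per_strand
    bad_deg = [
        (i, topology.degree(i))
        for i in range(1, n + 1)
        if not (1 <= topology.degree(i) <= config.max_contacts_per_strand)
    ]
    checks["degree_bounds"] = CheckResult(not bad_deg, bad_deg)

    # each residue in at most 2 active residue contacts
    res_count: dict[int, int] = {}
    for c in contacts:
        for k, l in c.residue_pairs:
            res_count[k] = res_count.get(k, 0) + 1
            res_count[l] = res_count.get(l, 0) + 1
    over = [(r, m) for r, m in sorted(res_count.items()) if m > 2]
    checks["residue_contact_cap"] = CheckResult(not over, over)

    # per-strand residue budget
    bad_budget = []
    for i in range(1, n + 1):
        lo, hi = config.residue_budget(protein.strand(i).length)
        tot = sum(c.n_pairs for c in topology.contacts_of(i))
        if not (lo <= tot <= hi):
            bad_budget.append((i, tot, lo, hi))
    checks["residue_budget"] = CheckResult(not bad_budget, bad_budget)

    # triple-overlap exclusion: three partners may not all overlap pairwise
    # on the shared strand
    bad_triple = []
    for s in range(1, n + 1):
        cs = topology.contacts_of(s)
        for trio in combinations(cs, 3):
            ivs = [c.interval_on(s) for c in trio]
            if all(
                _intervals_overlap(ivs[a], ivs[b]) for a, b in combinations(range(3), 2)
            ):
                bad_triple.append((s, [c.pair for c in trio]))
        checks["triple_overlap"] = CheckResult(not bad_triple, bad_triple)
    if "triple_overlap" not in checks:
        checks["triple_overlap"] = CheckResult(True)

    # 3-contact strands: at most 2 partners outside {i-1, i+1, 1, N}
    bad_edge = []
    for i in range(1, n + 1):
        allowed = {i - 1, i + 1, 1, n}
        cs = topology.contacts_of(i)
        if config.edge_rule_orientations == "antiparallel":
            cs = [c for c in cs if c.orientation is Orientation.ANTIPARALLEL]
        outside = [c.pair for c in cs if (c.i if c.j == i else c.j) not in allowed]
        if len(outside) > 2:
            bad_edge.append((i, outside))
    checks["edge_rule"] = CheckResult(not bad_edge, bad_edge)

    # non-local contacts need an enabling neighbor contact
    active_pairs = {c.pair for c in contacts}
    bad_nl = []
    for c in contacts:
        if c.j - c.i < config.nonlocal_threshold:
            continue
        enabling = nonlocal_enabling_pairs(protein, c.i, c.j, config)
        if not (enabling & active_pairs):
            bad_nl.append(c.pair)
    checks["nonlocal_enabling"] = CheckResult(not bad_nl, bad_nl)

    # pretzel exclusion on every strand quartet
    bad_pretzel = []
    for i, j, k, l in combinations(range(1, n + 1), 4):
        chain1 = [(i, k), (i, l), (j, l)]
        chain2 = [(i, k), (j, k), (j, l)]
        for chain in (chain1, chain2):
            if sum(1 for p in chain if p in active_pairs) > 2:
                bad_pretzel.append(((i, j, k, l), chain))
    checks["pretzel"] = CheckResult(not bad_pretzel, bad_pretzel)

    # every non-local contact belongs to an interlock
    nl_pairs = [
        p for p in active_pairs if p[1] - p[0] >= config.nonlocal_threshold
    ]
    bad_il = []
    il_count: dict[tuple[int, int], int] = {}
    for i, k in nl_pairs:
        partners = [
            (j, l)
            for (j, l) in nl_pairs
            if (i < j < k < l) or (j < i < l < k)
        ]
        il_count[(i, k)] = len(partners)
        if not partners:
            bad_il.append((i, k))
    checks["interlock"] = CheckResult(not bad_il, bad_il)
    multi = [p for p, m in il_count.items() if m > 1]
    if multi:
        warnings.append({"interlock_multiplicity": multi})

    # terminal-strand sets: one per five strands
    order = _terminal_sorted(protein, config)
    bad_ts = []
    for k in range(1, n // config.terminal_set_stride + 1):
        first = order[: 2 * k]
        ones = sum(1 for i in first if topology.degree(i) == 1)
        if ones < k:
            bad_ts.append((k, first, ones))
    checks["terminal_sets"] = CheckResult(not bad_ts, bad_ts)

    # hydrogen-bond budget on total residue contacts
    lo, hi = config.hbond_bounds(protein.n_beta_residues)
    w_total = sum(c.n_pairs for c in contacts)
    checks["hbond_budget"] = CheckResult(
        lo <= w_total <= hi, [] if lo <= w_total <= hi else [(w_total, lo, hi)]
    )

    # no cyclic (barrel-like) arrangements
    cycles = find_cycles(topology, n)
    checks["acyclic"] = CheckResult(not cycles, cycles)

    # consistent face assignment
    ok2, witness = is_two_colorable(topology)
    checks["two_colorable"] = CheckResult(ok2, [] if ok2 else [witness])

    return ValidationReport(checks=checks, warnings=warnings)
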