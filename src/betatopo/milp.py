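"""Mixed-integer linear model for ranked β-sheet topology prediction.

Binary variables y^A_ij / y^P_ij select an antiparallel or parallel contact
for each alignable strand pair (i < j); continuous w_kl variables mark
hydrogen-bonded residue pairs and are tied to the strand variables by
equality, so their integrality is implied.  The objective maximizes the sum
of locality-corrected contact potentials over selected contacts.  Ranked
solutions are produced by re-solving after adding an integer cut that
excludes the incumbent's strand-contact assignment; solutions containing a
cyclic (barrel-like) contact graph or failing the two-colorability check
are cut away without consuming a rank.

Solved with HiGHS through :func:`scipy.optimize.milp` (single-threaded and
deterministic for a fixed input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .checks import (
    find_cycles,
    is_two_colorable,
    nonlocal_enabling_pairs,
    _terminal_sorted,
)
from .datamodel import (
    ModelConfig,
    Orientation,
    ProteinRecord,
    SheetTopology,
    ValidationError,
)
from .enumeration import aln_to_contact
from .scoring import ScoredPairs

__all__ = [
    "TopologyModel",
    "build_model",
    "add_structural_constraints",
    "add_geometric_constraints",
    "add_topological_constraints",
    "add_hbond_budget",
    "add_integer_cut",
    "solve_ranked",
]

_INF = np.inf


@dataclass
class TopologyModel:
    """Variables, objective and constraint rows of one instance."""

    protein: ProteinRecord
    scored_pairs: ScoredPairs
    config: ModelConfig
    #: (i, j, Orientation) per strand-contact binary, in deterministic order
    y_keys: list = field(default_factory=list)
    #: (k, l) residue pair per w variable
    w_keys: list = field(default_factory=list)
    #: strand index per z (exactly-one-contact indicator); empty if unused
    z_keys: list = field(default_factory=list)
    objective: np.ndarray | None = None
    rows: list = field(default_factory=list)  # (coef dict, lb, ub)
    cuts: list = field(default_factory=list)
    status: str = "built"

    # -- index helpers -----------------------------------------------------

    @property
    def n_vars(self) -> int:
        return len(self.y_keys) + len(self.w_keys) + len(self.z_keys)

    def y_index(self, i: int, j: int, orientation: Orientation) -> int | None:
        try:
            return self.y_keys.index((i, j, orientation))
        except ValueError:
            return None

    def y_indices_of_pair(self, i: int, j: int) -> list[int]:
        return [
            idx for idx, (a, b, _o) in enumerate(self.y_keys) if (a, b) == (i, j)
        ]

    def y_indices_of_strand(self, s: int) -> list[int]:
        return [
            idx for idx, (a, b, _o) in enumerate(self.y_keys) if s in (a, b)
        ]

    def w_index(self, k: int, l: int) -> int:
        return len(self.y_keys) + self.w_keys.index((k, l))

    def z_index(self, s: int) -> int:
        return len(self.y_keys) + len(self.w_keys) + self.z_keys.index(s)

    def add_row(self, coefs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append((coefs, lb, ub))

    # -- assembly for the solver -------------------------------------------

    def _matrices(self):
        nv = self.n_vars
        all_rows = self.rows + self.cuts
        data, ri, ci = [], [], []
        lbs, ubs = [], []
        for r, (coefs, lb, ub) in enumerate(all_rows):
            for c, v in coefs.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
            lbs.append(lb)
            ubs.append(ub)
        a = sparse.csr_matrix((data, (ri, ci)), shape=(len(all_rows), nv))
        return a, np.array(lbs), np.array(ubs)

    def solve(self):
        a, lb, ub = self._matrices()
        integrality = np.concatenate(
            [
                np.ones(len(self.y_keys)),
                np.zeros(len(self.w_keys)),  # equality-linked: integrality implied
                np.ones(len(self.z_keys)),
            ]
        )
        options = {"presolve": True, "mip_rel_gap": self.config.solver_gap}
        if self.config.solver_time_limit:
            options["time_limit"] = self.config.solver_time_limit
        res = milp(
            c=self.objective,
            constraints=LinearConstraint(a, lb, ub),
            integrality=integrality,
            bounds=Bounds(0, 1),
            options=options,
        )
        self.status = res.status
        return res

    def topology_from_solution(self, x: np.ndarray, rank: int = 0) -> SheetTopology:
        contacts = []
        objective = 0.0
        for idx, (i, j, o) in enumerate(self.y_keys):
            if x[idx] > 0.5:
                aln = self.scored_pairs.get(i, j, o)
                contacts.append(aln_to_contact(aln))
                objective += aln.corrected_score
        contacts.sort(key=lambda c: (c.i, c.j))
        return SheetTopology(contacts=tuple(contacts), objective=objective, rank=rank)


def build_model(
    protein: ProteinRecord,
    scored_pairs: ScoredPairs,
    config: ModelConfig | None = None,
) -> TopologyModel:
    """Construct the full model: variables, objective, all constraint families."""
    config = config or ModelConfig()
    n = protein.n_strands
    if n < 3:
        raise ValidationError("model requires at least 3 strands")

    y_keys = sorted(
        ((i, j, o) for (i, j, o) in dict(scored_pairs.items())),
        key=lambda t: (t[0], t[1], t[2].value),
    )
    for s in range(1, n + 1):
        if not any(s in (i, j) for i, j, _o in y_keys):
            raise ValidationError(
                f"strand {s} has no alignable partner: model infeasible by "
                f"construction (every strand needs at least one contact)"
            )
    w_set = set()
    for (i, j, o) in y_keys:
        aln = scored_pairs.get(i, j, o)
        w_set.update(aln.pairs)
    w_keys = sorted(w_set)

    z_keys = list(range(1, n + 1)) if n // config.terminal_set_stride >= 1 else []

    model = TopologyModel(
        protein=protein,
        scored_pairs=scored_pairs,
        config=config,
        y_keys=y_keys,
        w_keys=w_keys,
        z_keys=z_keys,
    )
    # maximize sum of corrected scores -> minimize the negation
    c = np.zeros(model.n_vars)
    for idx, (i, j, o) in enumerate(y_keys):
        c[idx] = -scored_pairs.get(i, j, o).corrected_score
    model.objective = c

    add_structural_constraints(model)
    add_geometric_constraints(model, config)
    add_topological_constraints(model, config)
    add_hbond_budget(model, protein, config)
    return model


def add_structural_constraints(model: TopologyModel) -> TopologyModel:
    """Linking, orientation exclusivity and cardinality constraints.

    w_kl is linked by *equality* to the strand binaries whose best alignment
    realizes the pair (an upper-bound link would let the solver zero all w
    and vacuously satisfy every residue-level constraint); each pair takes
    at most one orientation; each residue sits in ≤ 2 contacts; each strand
    has 1..max contacts; a non-barrel protein has at most N−1 contacts.
    """
    cfg = model.config
    n = model.protein.n_strands

    # w = sum of supporting y (equality link)
    supporters: dict[tuple[int, int], list[int]] = {w: [] for w in model.w_keys}
    for idx, (i, j, o) in enumerate(model.y_keys):
        for p in model.scored_pairs.get(i, j, o).pairs:
            supporters[p].append(idx)
    for p, ys in supporters.items():
        coefs = {model.w_index(*p): 1.0}
        for yi in ys:
            coefs[yi] = coefs.get(yi, 0.0) - 1.0
        model.add_row(coefs, 0.0, 0.0)

    # one orientation per pair
    for i, j in model.scored_pairs.pairs():
        idxs = model.y_indices_of_pair(i, j)
        if len(idxs) > 1:
            model.add_row({idx: 1.0 for idx in idxs}, -_INF, 1.0)

    # each residue in at most two active residue contacts
    by_res: dict[int, list[int]] = {}
    for p in model.w_keys:
        wi = model.w_index(*p)
        for r in p:
            by_res.setdefault(r, []).append(wi)
    for r, ws in sorted(by_res.items()):
        if len(ws) > 2:
            model.add_row({wi: 1.0 for wi in ws}, -_INF, 2.0)

    # strand degree in [1, max]; total <= N - 1
    for s in range(1, n + 1):
        idxs = model.y_indices_of_strand(s)
        model.add_row({idx: 1.0 for idx in idxs}, 1.0, float(cfg.max_contacts_per_strand))
    model.add_row({idx: 1.0 for idx in range(len(model.y_keys))}, -_INF, float(n - 1))
    return model


def add_geometric_constraints(model: TopologyModel, config: ModelConfig) -> TopologyModel:
    """Residue budgets, triple-overlap exclusion and the edge rule."""
    protein = model.protein
    sp = model.scored_pairs
    n = protein.n_strands

    # per-strand residue-contact budget: B_lo(i) <= sum overlap*y <= B_hi(i)
    for s in range(1, n + 1):
        lo, hi = config.residue_budget(protein.strand(s).length)
        coefs = {}
        for idx in model.y_indices_of_strand(s):
            i, j, o = model.y_keys[idx]
            coefs[idx] = float(sp.get(i, j, o).n_pairs)
        model.add_row(coefs, float(lo), float(hi))

    # three partners of one strand may not all overlap pairwise on it
    for s in range(1, n + 1):
        incident = model.y_indices_of_strand(s)
        partners: dict[int, list[int]] = {}
        for idx in incident:
            i, j, _o = model.y_keys[idx]
            partners.setdefault(j if i == s else i, []).append(idx)
        for p1, p2, p3 in combinations(sorted(partners), 3):
            for i1, i2, i3 in product(partners[p1], partners[p2], partners[p3]):
                ivs = [
                    sp.get(*model.y_keys[idx][:2], model.y_keys[idx][2]).interval_on(s)
                    for idx in (i1, i2, i3)
                ]
                if all(
                    min(a[1], b[1]) - max(a[0], b[0]) >= 0
                    for a, b in combinations(ivs, 2)
                ):
                    model.add_row({i1: 1.0, i2: 1.0, i3: 1.0}, -_INF, 2.0)

    # a 3-contact strand keeps at least one contact among its sequence
    # neighbors or the two edge strands
    for s in range(1, n + 1):
        allowed = {s - 1, s + 1, 1, n}
        idxs = []
        for idx in model.y_indices_of_strand(s):
            i, j, o = model.y_keys[idx]
            partner = j if i == s else i
            if partner in allowed:
                continue
            if (
                config.edge_rule_orientations == "antiparallel"
                and o is not Orientation.ANTIPARALLEL
            ):
                continue
            idxs.append(idx)
        if len(idxs) > 2:
            model.add_row({idx: 1.0 for idx in idxs}, -_INF, 2.0)
    return model


def add_topological_constraints(model: TopologyModel, config: ModelConfig) -> TopologyModel:
    """Non-local enabling, pretzel and interlock rules, terminal sets."""
    protein = model.protein
    n = protein.n_strands
    pairs_with_vars = set(model.scored_pairs.pairs())

    # non-local contact requires an enabling neighbor contact
    for (i, j) in sorted(pairs_with_vars):
        if j - i < config.nonlocal_threshold:
            continue
        coefs = {idx: 1.0 for idx in model.y_indices_of_pair(i, j)}
        for (a, b) in nonlocal_enabling_pairs(protein, i, j, config):
            for idx in model.y_indices_of_pair(a, b):
                coefs[idx] = coefs.get(idx, 0.0) - 1.0
        model.add_row(coefs, -_INF, 0.0)

    # pretzel: forbid both crossing 3-chains of every strand quartet
    for i, j, k, l in combinations(range(1, n + 1), 4):
        for chain in ([(i, k), (i, l), (j, l)], [(i, k), (j, k), (j, l)]):
            if not all(p in pairs_with_vars for p in chain):
                continue
            coefs: dict[int, float] = {}
            for p in chain:
                for idx in model.y_indices_of_pair(*p):
                    coefs[idx] = 1.0
            model.add_row(coefs, -_INF, 2.0)

    # interlock: every non-local contact needs a bracketing non-local partner
    nonlocal_pairs = [
        p for p in sorted(pairs_with_vars) if p[1] - p[0] >= config.nonlocal_threshold
    ]
    for (i, k) in nonlocal_pairs:
        coefs = {idx: 1.0 for idx in model.y_indices_of_pair(i, k)}
        for (j, l) in nonlocal_pairs:
            if (i < j < k < l) or (j < i < l < k):
                for idx in model.y_indices_of_pair(j, l):
                    coefs[idx] = coefs.get(idx, 0.0) - 1.0
        model.add_row(coefs, -_INF, 0.0)

    # terminal sets: among the 2k least hydrophobic/shortest strands, at
    # least k have exactly one contact (one set per five strands)
    if model.z_keys:
        m = float(config.max_contacts_per_strand)
        for s in model.z_keys:
            coefs = {idx: 1.0 for idx in model.y_indices_of_strand(s)}
            coefs[model.z_index(s)] = m - 1.0
            model.add_row(coefs, -_INF, m)
        order = _terminal_sorted(protein, config)
        for k in range(1, n // config.terminal_set_stride + 1):
            coefs = {model.z_index(s): 1.0 for s in order[: 2 * k]}
            model.add_row(coefs, float(k), _INF)
    return model


def add_hbond_budget(
    model: TopologyModel, protein: ProteinRecord, config: ModelConfig
) -> TopologyModel:
    """Total residue contacts within ±tolerance of 0.638 · (β-residues)."""
    lo, hi = config.hbond_bounds(protein.n_beta_residues)
    coefs = {model.w_index(*p): 1.0 for p in model.w_keys}
    model.add_row(coefs, float(lo), float(hi))
    return model


def add_integer_cut(model: TopologyModel, topology: SheetTopology) -> TopologyModel:
    """Exclude the incumbent strand-contact assignment.

    With Z_O the active strand binaries (cardinality c):
    sum(Z_O) − sum(Z_Z) ≤ c − 1.  Residue variables never enter cuts.
    """
    active = {(c.i, c.j, c.orientation) for c in topology.contacts}
    coefs = {}
    cardinality = 0
    for idx, key in enumerate(model.y_keys):
        if key in active:
            coefs[idx] = 1.0
            cardinality += 1
        else:
            coefs[idx] = -1.0
    model.cuts.append((coefs, -_INF, float(cardinality - 1)))
    return model


def solve_ranked(
    protein: ProteinRecord,
    scored_pairs: ScoredPairs,
    config: ModelConfig | None = None,
    K: int | None = None,
    log: list | None = None,
) -> list[SheetTopology]:
    """Iteratively solve for the K best feasible topologies.

    Optimal solutions whose contact graph contains a cycle (sub-barrel) or
    whose incompatibility graph is not two-colorable are cut away without
    consuming a rank.  Returns up to K topologies with non-increasing
    objectives; fewer when the model runs out of feasible solutions.
    """
    config = config or ModelConfig()
    K = K or config.K
    model = build_model(protein, scored_pairs, config)
    out: list[SheetTopology] = []
    iteration = 0
    max_iterations = 100 * K + 1000  # guards against pathological cut loops
    while len(out) < K and iteration < max_iterations:
        iteration += 1
        res = model.solve()
        if res.status != 0:
            if log is not None:
                log.append(
                    {
                        "iteration": iteration,
                        "event": "stop",
                        "status": int(res.status),
                        "message": str(res.message),
                    }
                )
            break
        topo = model.topology_from_solution(res.x)
        cycles = find_cycles(topo, protein.n_strands)
        colorable, _ = is_two_colorable(topo)
        if cycles:
            cut_type = "cycle"
        elif not colorable:
            cut_type = "coloring"
        else:
            cut_type = "rank"
            topo = SheetTopology(
                contacts=topo.contacts, objective=topo.objective, rank=len(out) + 1
            )
            out.append(topo)
        if log is not None:
            log.append(
                {
                    "iteration": iteration,
                    "objective": topo.objective,
                    "cut": cut_type,
                    "rank": topo.rank if cut_type == "rank" else None,
                }
            )
        add_integer_cut(model, topo)
    return out
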