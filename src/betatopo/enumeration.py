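"""Exact combinatorics of sheet-motif space and exhaustive ranked search.

A *motif* is a linear order of the strands within a sheet together with the
parallel/antiparallel orientation of each adjacent pair.  Reading a sheet
right-to-left gives the same physical object, so motifs are canonicalized
under reversal; this reflection symmetry is exactly the factor 2 in the
closed-form count n!/2 · 2^(n−1).

``brute_force_rank`` enumerates *all* candidate contact assignments of a
small protein, filters them through the same validation code path the
solver's solutions must pass, and ranks by the same objective — the
ground-truth oracle against which the optimization model is checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Iterator

from .checks import validate_topology
from .datamodel import ModelConfig, Orientation, ProteinRecord, SheetTopology
from .scoring import ScoredPairs

__all__ = ["Motif", "count_motifs", "enumerate_motifs", "brute_force_rank"]

#: full enumeration above this many strands is refused (motif count explodes)
ENUMERATION_CAP = 7


@dataclass(frozen=True)
class Motif:
    """Canonical sheet motif: strand order plus adjacent-pair orientations."""

    order: tuple[int, ...]
    orientations: tuple[Orientation, ...]

    def __post_init__(self) -> None:
        if len(self.orientations) != len(self.order) - 1:
            raise ValueError("need one orientation per adjacent pair")

    def reversed_form(self) -> tuple[tuple[int, ...], tuple[Orientation, ...]]:
        return self.order[::-1], self.orientations[::-1]

    @property
    def is_canonical(self) -> bool:
        key = (self.order, tuple(o.value for o in self.orientations))
        ro, rs = self.reversed_form()
        rkey = (ro, tuple(o.value for o in rs))
        return key <= rkey


def count_motifs(n: int) -> int:
    """Number of distinct sheet motifs for n strands: n!/2 · 2^(n−1).

    Derivation: n! linear orders × 2^(n−1) orientation assignments for the
    n−1 adjacent pairs, divided by 2 because a sheet and its mirror-read
    (reversed order, reversed orientation list) are the same motif.  No
    order equals its own reversal for n ≥ 2, so the quotient is exact.
    """
    if n < 2:
        raise ValueError(f"motif counting requires n >= 2, got {n}")
    return math.factorial(n) * 2 ** (n - 1) // 2


def enumerate_motifs(n: int, cap: int = ENUMERATION_CAP) -> Iterator[Motif]:
    """Stream every canonical motif exactly once (n ≤ cap)."""
    if n < 2:
        raise ValueError(f"motif enumeration requires n >= 2, got {n}")
    if n > cap:
        raise ValueError(
            f"refusing to enumerate n={n} (> cap {cap}): would produce "
            f"{count_motifs(n)} motifs"
        )
    both = (Orientation.ANTIPARALLEL, Orientation.PARALLEL)
    for order in permutations(range(1, n + 1)):
        if order > order[::-1]:
            continue  # reversal will be (or was) emitted in canonical form
        for orients in product(both, repeat=n - 1):
            yield Motif(order=order, orientations=orients)


def brute_force_rank(
    protein: ProteinRecord,
    scored_pairs: ScoredPairs,
    config: ModelConfig | None = None,
    K: int | None = None,
) -> list[SheetTopology]:
    """Exhaustively enumerate, validate and rank all feasible topologies.

    Every subset of alignable strand pairs of feasible size (each strand
    needs a contact, a forest has at most N−1 edges), in every orientation
    assignment, is materialized as a topology with the stored best
    alignments and filtered through ``validate_topology``.  Survivors are
    ranked by total corrected contact potential.  Intended for n ≤ 6.
    """
    config = config or ModelConfig()
    K = K or config.K
    n = protein.n_strands
    if n > 6:
        raise ValueError(f"brute_force_rank supports n <= 6, got {n}")
    pair_list = scored_pairs.pairs()
    candidates: list[SheetTopology] = []
    min_size = max(1, math.ceil(n / 2))  # every strand needs >= 1 contact
    for size in range(min_size, n):
        for subset in combinations(pair_list, size):
            orient_choices = [scored_pairs.orientations(i, j) for i, j in subset]
            for orients in product(*orient_choices):
                contacts = []
                objective = 0.0
                for (i, j), o in zip(subset, orients):
                    aln = scored_pairs.get(i, j, o)
                    contacts.append(aln_to_contact(aln))
                    objective += aln.corrected_score
                topo = SheetTopology(contacts=tuple(contacts), objective=objective)
                if validate_topology(topo, protein, config).ok:
                    candidates.append(topo)
    candidates.sort(key=lambda t: (-t.objective, sorted(t.oriented_pairs)))
    out = []
    for rank, t in enumerate(candidates[:K], start=1):
        out.append(SheetTopology(contacts=t.contacts, objective=t.objective, rank=rank))
    return out


def aln_to_contact(aln):
    """Materialize a StrandContact from a stored best alignment."""
    from .datamodel import StrandContact

    return StrandContact(
        i=aln.i,
        j=aln.j,
        orientation=aln.orientation,
        offset=aln.offset,
        residue_pairs=tuple(
            (k, l) if k < l else (l, k) for k, l in aln.pairs
        ),
    )
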