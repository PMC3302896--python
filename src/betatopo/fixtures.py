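"""Deterministic synthetic proteins with planted, constraint-satisfying
topologies and matched potential tables.

Construction
------------
Strand lengths are drawn so the two sheet-terminal strands are strictly the
shortest (hydrophobic-collapse ordering: short, less buried strands sit at
the sheet edge and make one contact).  The planted topology is a ladder of
sheet-adjacent contacts — either sequence order 1–2–…–N or, optionally for
N ≥ 5, a greek-key-like order 1–4–3–2–5–…–N containing one interlocked pair
of non-local contacts.  Contact overlaps are fitted to the hydrogen-bond
budget 0.638·(β-residues) ± 15% by shrinking the largest registers first.

Sequences are poly-valine strands joined by glycine loops.  Each planted
contact receives a unique *marker* residue pair: two residue types that
occur nowhere else in the protein, placed at positions aligned by the
planted register, whose table entry is boosted by ~2 score units per
aligned position.  All other residue-pair scores are a small uniform
background (2⁻⁴, exactly representable), so the planted register is the
unique score optimum for its pair and orientation, the wrong orientation
scores strictly less (marker positions are chosen so its marker-aligned
register has a smaller overlap), and every non-planted strand pair scores
near zero.  The generator verifies all of this — best alignments equal the
planted ones and the planted topology passes full validation — and retries
with a derived sub-seed until the contract holds.

These fixtures emulate the *combinatorial* structure of real sheet
topologies (cardinalities, budgets, locality, interlocks), not real
energetics: the potential is designed, not learned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .checks import validate_topology
from .datamodel import (
    ModelConfig,
    Orientation,
    ProteinRecord,
    SheetTopology,
    Strand,
    StrandContact,
    ValidationError,
)
from .scoring import PotentialTable, ScoredPairs, _alignment_pairs, score_all_pairs

__all__ = ["Fixture", "make_fixture", "write_fixture_files", "write_dssp"]

#: uniform background pair score (2^-4: exact in binary floating point)
BACKGROUND = 0.0625
#: score units per aligned position of a planted contact
BIAS_PER_PAIR = 2.0

_LOOP = "G"
_DOMINANT = "V"
_MARKER_POOL = "ACDEFHIKLMNPQRSTWY"  # everything except loop G and dominant V


@dataclass(frozen=True)
class Fixture:
    protein: ProteinRecord
    planted: SheetTopology
    table: PotentialTable
    seed: int
    scored: ScoredPairs

    @property
    def native_pairs(self) -> dict:
        """Residue-pair registers per strand pair, for register accuracy."""
        return {c.pair: set(c.residue_pairs) for c in self.planted.contacts}


def _sheet_order(n: int, interlock: bool) -> list[int]:
    if interlock:
        return [1, 4, 3, 2, 5] + list(range(6, n + 1))
    return list(range(1, n + 1))


def _fit_overlaps(
    order: list[int],
    lengths: dict[int, int],
    config: ModelConfig,
) -> dict[tuple[int, int], int] | None:
    """Contact overlaps meeting the H-bond budget and per-strand budgets."""
    contacts = [
        (min(a, b), max(a, b)) for a, b in zip(order, order[1:])
    ]
    targets = {c: min(lengths[c[0]], lengths[c[1]]) for c in contacts}
    lo, hi = config.hbond_bounds(sum(lengths.values()))

    def strand_sum(s: int) -> int:
        return sum(t for c, t in targets.items() if s in c)

    while sum(targets.values()) > hi:
        candidates = [
            c
            for c, t in targets.items()
            if t > 3
            and all(strand_sum(s) - 1 >= lengths[s] - config.residue_budget_lo_slack
                    for s in c)
        ]
        if not candidates:
            return None
        candidates.sort(key=lambda c: (-targets[c], c))
        targets[candidates[0]] -= 1
    if sum(targets.values()) < lo:
        return None
    for s in lengths:
        b_lo, b_hi = config.residue_budget(lengths[s])
        if not (b_lo <= strand_sum(s) <= b_hi):
            return None
    return targets


def _rival_overlap(
    orientation: Orientation, a: int, b: int, li: int, lj: int
) -> int:
    """Overlap of the opposite-orientation register aligning local (a, b)."""
    if orientation is Orientation.PARALLEL:
        t = a + b - (lj - 1)  # antiparallel register through (a, b)
    else:
        t = a - b  # parallel register through (a, b)
    return max(0, min(li, lj + t) - max(0, t))


def _attempt(n: int, seed: int, attempt: int, config: ModelConfig) -> Fixture | None:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, n, attempt])

    interlock = n >= 5 and rng.random() < 0.5
    order = _sheet_order(n, interlock)
    lengths = {}
    for s in range(1, n + 1):
        if s in (order[0], order[-1]):
            lengths[s] = int(rng.integers(3, 5))  # sheet-terminal: short
        else:
            lengths[s] = int(rng.integers(5, 8))

    targets = _fit_overlaps(order, lengths, config)
    if targets is None:
        return None

    # chain layout: loops of >= 1 glycine between strands
    gaps = [int(rng.integers(1, 4))] + [
        int(rng.integers(2, 5)) for _ in range(n - 1)
    ] + [int(rng.integers(1, 4))]
    starts = {}
    pos = gaps[0] + 1
    for s in range(1, n + 1):
        starts[s] = pos
        pos += lengths[s] + gaps[s]
    n_res = pos - 1  # last strand end + C-terminal loop
    seq = [_LOOP] * n_res
    for s in range(1, n + 1):
        for k in range(lengths[s]):
            seq[starts[s] - 1 + k] = _DOMINANT

    # markers and planted registers
    pool = list(_MARKER_POOL)
    used_positions: dict[int, set[int]] = {s: set() for s in range(1, n + 1)}
    planted_spec = []  # (i, j, orientation, offset, local pairs, marker letters)
    contacts_seq = [(min(a, b), max(a, b)) for a, b in zip(order, order[1:])]
    orientations = {
        c: (Orientation.ANTIPARALLEL if rng.random() < 0.5 else Orientation.PARALLEL)
        for c in contacts_seq
    }
    for c in contacts_seq:
        i, j = c
        li, lj = lengths[i], lengths[j]
        o_c = targets[c]
        orient = orientations[c]
        offsets = []
        for t in range(-(lj - config.min_overlap), li - config.min_overlap + 1):
            if min(li, lj + t) - max(0, t) == o_c:
                offsets.append(t)
        if not offsets:
            return None
        t_star = int(offsets[rng.integers(len(offsets))])
        a_lo, a_hi = max(0, t_star), min(li - 1, lj - 1 + t_star)
        local_pairs = []
        for a in range(a_lo, a_hi + 1):
            b = (a - t_star) if orient is Orientation.PARALLEL else (lj - 1 - a + t_star)
            local_pairs.append((a, b))
        candidates = [
            (a, b)
            for a, b in local_pairs
            if _rival_overlap(orient, a, b, li, lj) < o_c
            and a not in used_positions[i]
            and b not in used_positions[j]
        ]
        if not candidates or len(pool) < 2:
            return None
        candidates.sort(key=lambda ab: (_rival_overlap(orient, *ab, li, lj), ab))
        a_m, b_m = candidates[0]
        u, v = pool.pop(0), pool.pop(0)
        used_positions[i].add(a_m)
        used_positions[j].add(b_m)
        seq[starts[i] - 1 + a_m] = u
        seq[starts[j] - 1 + b_m] = v
        planted_spec.append((i, j, orient, t_star, local_pairs, (u, v)))

    sequence = "".join(seq)
    strands = tuple(
        Strand(
            index=s,
            start=starts[s],
            end=starts[s] + lengths[s] - 1,
            residues=sequence[starts[s] - 1 : starts[s] - 1 + lengths[s]],
        )
        for s in range(1, n + 1)
    )
    protein = ProteinRecord(id=f"synth_n{n}_s{seed}", sequence=sequence, strands=strands)

    # potential table: uniform background plus per-contact marker boosts
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    table_df = pd.DataFrame(BACKGROUND, index=aas, columns=aas, dtype=float)
    for i, j, orient, t_star, local_pairs, (u, v) in planted_spec:
        boost = BIAS_PER_PAIR * targets[(i, j)]
        table_df.at[u, v] = boost
        table_df.at[v, u] = boost
    table = PotentialTable(table_df, name=f"planted_n{n}_s{seed}")

    # materialize the planted topology
    contacts = []
    objective = 0.0
    for i, j, orient, t_star, local_pairs, _letters in planted_spec:
        pairs = tuple(
            (starts[i] + a, starts[j] + b) for a, b in local_pairs
        )
        raw = sum(table.score(sequence[k - 1], sequence[l - 1]) for k, l in pairs)
        objective += raw * config.locality_weight(j - i)
        contacts.append(
            StrandContact(
                i=i, j=j, orientation=orient, offset=t_star, residue_pairs=pairs
            )
        )
    contacts.sort(key=lambda c: (c.i, c.j))
    planted = SheetTopology(contacts=tuple(contacts), objective=objective, rank=1)

    # -- verify the construction contract ---------------------------------
    scored = score_all_pairs(protein, table, config)
    planted_keys = set()
    min_planted = min(
        scored.get(c.i, c.j, c.orientation).corrected_score
        if scored.get(c.i, c.j, c.orientation)
        else -np.inf
        for c in planted.contacts
    )
    for c in planted.contacts:
        aln = scored.get(c.i, c.j, c.orientation)
        if aln is None or aln.offset != c.offset or aln.pairs != c.residue_pairs:
            return None
        other = scored.get(
            c.i,
            c.j,
            Orientation.PARALLEL
            if c.orientation is Orientation.ANTIPARALLEL
            else Orientation.ANTIPARALLEL,
        )
        if other is not None and other.corrected_score >= aln.corrected_score:
            return None
        planted_keys.add((c.i, c.j, c.orientation))
    # local optimality: every planted edge beats every non-planted edge
    for (i, j, o), aln in scored.items():
        if (i, j, o) not in planted_keys and (i, j) not in targets:
            if aln.corrected_score >= min_planted:
                return None
    if not validate_topology(planted, protein, config).ok:
        return None
    return Fixture(protein=protein, planted=planted, table=table, seed=seed,
                   scored=scored)


def make_fixture(
    n_strands: int, seed: int, config: ModelConfig | None = None
) -> Fixture:
    """Deterministic synthetic protein with a planted feasible topology.

    Identical (n_strands, seed, config) give identical fixtures.  Raises
    when no valid construction is found within the attempt budget (does not
    happen for the supported range in practice).
    """
    if not (3 <= n_strands <= 10):
        raise ValidationError(
            f"fixtures support 3..10 strands, got {n_strands}"
        )
    config = config or ModelConfig()
    for attempt in range(200):
        fx = _attempt(n_strands, seed, attempt, config)
        if fx is not None:
            return fx
    raise RuntimeError(
        f"could not construct a valid fixture for n={n_strands}, seed={seed}"
    )


def write_fixture_files(fixture: Fixture, outdir) -> dict[str, Path]:
    """Emit FASTA, strand TSV, potential TSV and native-topology JSON."""
    from . import fileio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{fixture.protein.id}.fasta",
        "strands": outdir / f"{fixture.protein.id}.strands.tsv",
        "potential": outdir / f"{fixture.protein.id}.potential.tsv",
        "native": outdir / f"{fixture.protein.id}.native.json",
    }
    fileio.write_fasta(fixture.protein, paths["fasta"])
    fileio.write_strand_table(fixture.protein, paths["strands"])
    fixture.table.to_tsv(paths["potential"])
    fileio.write_topologies([fixture.planted], paths["native"], protein=fixture.protein)
    return paths


def write_dssp(protein: ProteinRecord, path) -> None:
    """Emit a synthetic DSSP-format file for a ProteinRecord.

    Writes the fixed-column record layout DSSP v2 produces (only the
    residue, chain, amino-acid and summary-structure columns carry
    information; accessibility, H-bond and angle columns are zero-filled).
    """
    ss = ["-"] * protein.n_residues
    for s in protein.strands:
        for p in range(s.start, s.end + 1):
            ss[p - 1] = "E"
    for b, e in protein.helix_segments:
        for p in range(b, e + 1):
            ss[p - 1] = "H"
    with open(path, "w") as fh:
        fh.write(f"==== Synthetic secondary structure assignment for {protein.id} ====\n")
        fh.write(
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
            "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    "
            "X-CA   Y-CA   Z-CA\n"
        )
        for idx in range(1, protein.n_residues + 1):
            line = [" "] * 120
            line[0:5] = f"{idx:5d}"
            line[5:10] = f"{idx:5d}"
            line[11] = "A"
            line[13] = protein.sequence[idx - 1]
            line[16] = ss[idx - 1] if ss[idx - 1] != "-" else " "
            line[34:38] = f"{0:4d}"
            line[38:45] = f"{0:7d}"
            line[46:50] = f"{0.0:4.1f}"
            line[50:56] = f"{0:6d}"
            line[57:61] = f"{0.0:4.1f}"
            line[61:67] = f"{0:6d}"
            line[68:72] = f"{0.0:4.1f}"
            line[72:78] = f"{0:6d}"
            line[79:83] = f"{0.0:4.1f}"
            line[103:109] = f"{0.0:6.1f}"
            line[109:115] = f"{0.0:6.1f}"
            fh.write("".join(line).rstrip() + "\n")
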