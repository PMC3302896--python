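"""Strand-pair alignment and contact-potential scoring.

For every pair of strands and both orientations the best *gapless* register
is found by sliding one strand across the other.  The raw score (sum of
residue-pair potentials over aligned positions) is corrected for the local
bias of database-derived potentials by a per-separation multiplicative
weight.  The resulting corrected scores are the S^A/S^P coefficients of the
optimization objective, and the realized residue pairs define the
residue-contact incidence the model's constraints act on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .datamodel import (
    STANDARD_AA,
    FormatError,
    ModelConfig,
    Orientation,
    ProteinRecord,
    Strand,
    ValidationError,
)

__all__ = [
    "PotentialTable",
    "PairAlignment",
    "align_pair",
    "best_alignment",
    "enumerate_alignments",
    "locality_correct",
    "score_all_pairs",
    "ScoredPairs",
    "default_potential_table",
]


# Kyte-Doolittle hydropathy, used to synthesize the default pairing table.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PotentialTable:
    """Symmetric 20×20 residue-pair contact potential.

    Higher scores mean a more favorable cross-strand pairing.  Residues
    outside the standard 20 (stored as 'X') score 0 against everything.
    """

    scores: "pd.DataFrame"
    name: str = "unnamed"

    def __post_init__(self) -> None:
        df = self.scores
        if list(df.index) != list(df.columns):
            raise ValidationError("potential table rows and columns must match")
        if not np.all(np.isfinite(df.to_numpy(dtype=float))):
            raise ValidationError("potential table contains non-finite entries")
        if not np.allclose(df.to_numpy(dtype=float), df.to_numpy(dtype=float).T):
            raise ValidationError("potential table must be symmetric")

    def score(self, a: str, b: str) -> float:
        if a not in self.scores.index or b not in self.scores.index:
            return 0.0  # 'X' and anything unknown
        return float(self.scores.at[a, b])

    def scaled(self, c: float) -> "PotentialTable":
        return PotentialTable(self.scores * c, name=f"{self.name}*{c}")

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "PotentialTable":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse potential table {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df.astype(float), name=str(path))

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", float_format="%.6g")


def default_potential_table() -> PotentialTable:
    """Hydropathy-product pairing propensities.

    A simple stand-in for trained β-pairing potentials: hydrophobic residues
    pair favorably with each other (cross-strand packing of the sheet core),
    polar/charged pairs are mildly disfavored.  s(a,b) = kd(a)·kd(b)/20.25,
    bounded to roughly [−1, 1].
    """
    aas = list(STANDARD_AA)
    vals = np.array([[_KD[a] * _KD[b] / 20.25 for b in aas] for a in aas])
    df = pd.DataFrame(vals, index=aas, columns=aas)
    return PotentialTable(df, name="kd-product")


@dataclass(frozen=True)
class PairAlignment:
    """Best gapless register of strands ``i < j`` in one orientation.

    ``pairs`` are global residue positions (pos_in_i, pos_in_j).  ``offset``
    parameterizes the register: for parallel alignments strand-j local index
    b = a − offset; for antiparallel b = L_j − 1 − a + offset (a is the
    strand-i local index).
    """

    i: int
    j: int
    orientation: Orientation
    offset: int
    pairs: tuple[tuple[int, int], ...]
    raw_score: float
    corrected_score: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def overlap_i(self) -> int:
        return len(self.pairs)

    @property
    def overlap_j(self) -> int:
        return len(self.pairs)

    def interval_on(self, strand_index: int) -> tuple[int, int]:
        if strand_index == self.i:
            ks = [k for k, _ in self.pairs]
        elif strand_index == self.j:
            ks = [l for _, l in self.pairs]
        else:
            raise ValueError(f"strand {strand_index} not part of this alignment")
        return (min(ks), max(ks))


def _alignment_pairs(
    si: Strand, sj: Strand, orientation: Orientation, offset: int
) -> list[tuple[int, int]]:
    li, lj = si.length, sj.length
    pairs = []
    if orientation is Orientation.PARALLEL:
        a_lo = max(0, offset)
        a_hi = min(li - 1, lj - 1 + offset)
        for a in range(a_lo, a_hi + 1):
            b = a - offset
            pairs.append((si.start + a, sj.start + b))
    else:
        a_lo = max(0, offset)
        a_hi = min(li - 1, lj - 1 + offset)
        for a in range(a_lo, a_hi + 1):
            b = lj - 1 - a + offset
            pairs.append((si.start + a, sj.start + b))
    return pairs


def enumerate_alignments(
    si: Strand,
    sj: Strand,
    orientation: Orientation,
    table: PotentialTable,
    min_overlap: int = 2,
) -> Iterator[tuple[int, list[tuple[int, int]], float]]:
    """Yield (offset, pairs, raw_score) for every register with enough overlap."""
    li, lj = si.length, sj.length
    for offset in range(-(lj - min_overlap), li - min_overlap + 1):
        pairs = _alignment_pairs(si, sj, orientation, offset)
        if len(pairs) < min_overlap:
            continue
        score = sum(
            table.score(si.residues[k - si.start], sj.residues[l - sj.start])
            for k, l in pairs
        )
        yield offset, pairs, score


def align_pair(
    si: Strand,
    sj: Strand,
    orientation: Orientation,
    table: PotentialTable,
    config: ModelConfig | None = None,
) -> PairAlignment | None:
    """Best gapless alignment of two strands in one orientation.

    Returns None when no register reaches the minimum overlap ("no valid
    alignment": the pair is excluded from the model).  Ties are broken by
    smallest |offset|, then smallest offset.
    """
    config = config or ModelConfig()
    if si.index >= sj.index:
        raise ValidationError("align_pair requires strand i before strand j")
    best: tuple[float, int, int] | None = None  # (-score, |offset|, offset)
    best_pairs: list[tuple[int, int]] | None = None
    for offset, pairs, score in enumerate_alignments(
        si, sj, orientation, table, config.min_overlap
    ):
        key = (-score, abs(offset), offset)
        if best is None or key < best:
            best = key
            best_pairs = pairs
    if best is None:
        return None
    raw = -best[0]
    corrected = locality_correct(raw, si.index, sj.index, config)
    return PairAlignment(
        i=si.index,
        j=sj.index,
        orientation=orientation,
        offset=best[2],
        pairs=tuple(best_pairs),
        raw_score=raw,
        corrected_score=corrected,
    )


#: alias used by callers that think of it as "the best register"
best_alignment = align_pair


def locality_correct(raw_score: float, i: int, j: int, config: ModelConfig) -> float:
    """Apply the per-separation locality weight to a raw pair score."""
    if i >= j:
        raise ValidationError("locality_correct requires i < j")
    return raw_score * config.locality_weight(j - i)


class ScoredPairs:
    """Best alignments for all strand pairs of a protein, both orientations.

    Access is symmetric: ``sp.get(i, j, orient)`` equals ``sp.get(j, i,
    orient)``.  Pairs with no valid alignment are absent.
    """

    def __init__(self, protein: ProteinRecord, alignments: dict):
        self.protein = protein
        self._alignments = alignments  # {(i, j, Orientation): PairAlignment}

    def get(self, i: int, j: int, orientation: Orientation) -> PairAlignment | None:
        if i > j:
            i, j = j, i
        return self._alignments.get((i, j, orientation))

    def orientations(self, i: int, j: int) -> list[Orientation]:
        if i > j:
            i, j = j, i
        return [o for o in Orientation if (i, j, o) in self._alignments]

    def items(self):
        return self._alignments.items()

    def __len__(self) -> int:
        return len(self._alignments)

    def __iter__(self):
        return iter(self._alignments.values())

    def pairs(self) -> list[tuple[int, int]]:
        """Unordered strand pairs with at least one valid alignment."""
        seen = sorted({(i, j) for (i, j, _o) in self._alignments})
        return seen


def score_all_pairs(
    protein: ProteinRecord,
    table: PotentialTable,
    config: ModelConfig | None = None,
) -> ScoredPairs:
    """Best corrected alignment for every strand pair and orientation.

    Refuses proteins with fewer than 3 strands (single-pair instances carry
    no topology to predict).
    """
    config = config or ModelConfig()
    if protein.n_strands < 3:
        raise ValidationError(
            f"protein {protein.id}: topology prediction requires at least 3 "
            f"strands, got {protein.n_strands}"
        )
    out = {}
    strands = protein.strands
    for a in range(len(strands)):
        for b in range(a + 1, len(strands)):
            si, sj = strands[a], strands[b]
            for orient in Orientation:
                aln = align_pair(si, sj, orient, table, config)
                if aln is not None:
                    out[(si.index, sj.index, orient)] = aln
    return ScoredPairs(protein, out)
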