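"""Hand-construction helpers for proteins, contacts and topologies."""

from __future__ import annotations

from betatopo.datamodel import (
    Orientation,
    ProteinRecord,
    SheetTopology,
    Strand,
    StrandContact,
)
from betatopo.scoring import _alignment_pairs


def build_protein(lengths: list[int], gap: int = 3, pid: str = "toy") -> ProteinRecord:
    """Poly-valine strands of the given lengths joined by glycine loops."""
    seq = []
    strands = []
    pos = gap
    for idx, L in enumerate(lengths, start=1):
        seq.extend("G" * gap if idx > 1 else "G" * gap)
        start = len(seq) + 1
        seq.extend("V" * L)
        strands.append(Strand(index=idx, start=start, end=start + L - 1, residues="V" * L))
    seq.extend("G" * gap)
    return ProteinRecord(id=pid, sequence="".join(seq), strands=tuple(strands))


def build_contact(
    protein: ProteinRecord,
    i: int,
    j: int,
    orientation: Orientation = Orientation.ANTIPARALLEL,
    offset: int = 0,
) -> StrandContact:
    """Contact realizing the gapless register at the given offset."""
    pairs = _alignment_pairs(protein.strand(i), protein.strand(j), orientation, offset)
    return StrandContact(
        i=i, j=j, orientation=orientation, offset=offset, residue_pairs=tuple(pairs)
    )


def topology(*contacts: StrandContact) -> SheetTopology:
    return SheetTopology(contacts=tuple(sorted(contacts, key=lambda c: c.pair)))
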