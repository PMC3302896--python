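"""Readers and writers for the formats the tool touches.

Inputs: FASTA (sequence), DSSP output or a plain 3-column strand table
(strand segments), symmetric potential table TSV.  Outputs: topology report
JSON and a distance-restraint TSV.  All coordinates 1-based inclusive.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.PDB.DSSP import make_dssp_dict

from .datamodel import (
    STANDARD_AA,
    FormatError,
    ModelConfig,
    Orientation,
    ProteinRecord,
    SheetTopology,
    Strand,
    StrandContact,
    ValidationError,
    strands_from_intervals,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_strand_table",
    "write_strand_table",
    "read_dssp",
    "write_topologies",
    "read_topologies",
    "export_restraints",
]

_ALLOWED = set(STANDARD_AA) | {"X"}


def _normalize_sequence(seq: str, origin: str) -> str:
    """Uppercase, strip whitespace, map non-standard residues to 'X'."""
    out = []
    for ch in seq:
        if ch.isspace():
            continue
        if not ch.isalpha() and ch != "*":
            raise FormatError(f"{origin}: illegal character {ch!r} in sequence")
        up = ch.upper()
        out.append(up if up in STANDARD_AA else "X")
    return "".join(out)


def read_fasta(path) -> ProteinRecord:
    """Read the first record of a FASTA file as a ProteinRecord (no strands)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    rec = records[0]
    seq = _normalize_sequence(str(rec.seq), str(path))
    if not seq:
        raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
    return ProteinRecord(id=rec.id, sequence=seq)


def write_fasta(protein: ProteinRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{protein.id}\n")
        seq = protein.sequence
        for k in range(0, len(seq), 60):
            fh.write(seq[k : k + 60] + "\n")


def read_strand_table(path, protein: ProteinRecord) -> ProteinRecord:
    """Attach strands from a 3-column TSV (strand_id, start, end), 1-based.

    Rows are re-sorted by start position and strand indices re-derived from
    sequence order; ids in the file are not trusted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["strand_id", "start", "end"],
        )
    except Exception as exc:
        raise FormatError(f"cannot parse strand table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: no strand rows")
    # tolerate a header row
    if not str(df.iloc[0]["start"]).lstrip("-").isdigit():
        df = df.iloc[1:]
        if df.empty:
            raise FormatError(f"{path}: no strand rows")
    intervals = [(int(r.start), int(r.end)) for r in df.itertuples()]
    for b, e in intervals:
        if b > e:
            raise ValidationError(f"{path}: strand interval ({b}, {e}) has start > end")
        if b < 1 or e > protein.n_residues:
            raise ValidationError(
                f"{path}: interval ({b}, {e}) outside sequence "
                f"[1, {protein.n_residues}]"
            )
    ordered = sorted(intervals)
    for (b1, e1), (b2, e2) in zip(ordered, ordered[1:]):
        if b2 <= e1:
            raise ValidationError(
                f"{path}: strands ({b1}, {e1}) and ({b2}, {e2}) overlap"
            )
    return protein.with_strands(strands_from_intervals(protein.sequence, ordered))


def write_strand_table(protein: ProteinRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("# strand_id\tstart\tend (1-based inclusive)\n")
        for s in protein.strands:
            fh.write(f"{s.index}\t{s.start}\t{s.end}\n")


def _runs(codes: str, targets: set[str]) -> list[tuple[int, int]]:
    """Maximal runs (1-based inclusive) of positions whose code is in targets."""
    runs = []
    start = None
    for pos, c in enumerate(codes, start=1):
        if c in targets:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, len(codes)))
    return runs


def read_dssp(path, id: str | None = None) -> ProteinRecord:
    """Parse a DSSP output file into a ProteinRecord.

    Residues with code 'E' are grouped into maximal runs → strands (runs of
    every length are kept; length filtering is a model concern).  'H'/'G'/'I'
    runs become helix segments.  Chain breaks ('!') are dropped.
    """
    path = Path(path)
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse DSSP file {path}: {exc}") from exc
    if not keys:
        raise FormatError(f"{path}: no residue records")
    seq_chars = []
    ss_chars = []
    for key in keys:
        aa, ss = dssp_dict[key][0], dssp_dict[key][1]
        if aa == "!":
            continue
        up = aa.upper()
        seq_chars.append(up if up in STANDARD_AA else "X")
        ss_chars.append(ss)
    sequence = "".join(seq_chars)
    codes = "".join(ss_chars)
    strands = strands_from_intervals(sequence, _runs(codes, {"E"}))
    helices = tuple(_runs(codes, {"H", "G", "I"}))
    return ProteinRecord(
        id=id or path.stem, sequence=sequence, strands=strands, helix_segments=helices
    )


# -- topology report JSON --------------------------------------------------


def _contact_to_dict(c: StrandContact) -> dict:
    return {
        "i": c.i,
        "j": c.j,
        "orientation": c.orientation.value,
        "offset": c.offset,
        "residue_pairs": [list(p) for p in c.residue_pairs],
    }


def _contact_from_dict(d: dict) -> StrandContact:
    return StrandContact(
        i=int(d["i"]),
        j=int(d["j"]),
        orientation=Orientation.from_str(d["orientation"]),
        offset=int(d["offset"]),
        residue_pairs=tuple((int(k), int(l)) for k, l in d["residue_pairs"]),
    )


def write_topologies(
    topologies: list[SheetTopology],
    path,
    protein: ProteinRecord | None = None,
    config: ModelConfig | None = None,
) -> None:
    """Write a ranked topology list as a JSON report."""
    if not topologies:
        raise ValidationError("write_topologies requires a non-empty topology list")
    n_strands = protein.n_strands if protein else max(
        max(c.j for c in t.contacts) for t in topologies if t.contacts
    )
    doc = {
        "id": protein.id if protein else "unknown",
        "config_hash": config.config_hash() if config else None,
        "n_strands": n_strands,
        "topologies": [
            {
                "rank": t.rank,
                "objective": t.objective,
                "contacts": [_contact_to_dict(c) for c in t.contacts],
                "sheets": t.sheets(n_strands),
            }
            for t in topologies
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_topologies(path) -> list[SheetTopology]:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse topology JSON {path}: {exc}") from exc
    out = []
    for t in doc.get("topologies", []):
        out.append(
            SheetTopology(
                contacts=tuple(_contact_from_dict(c) for c in t["contacts"]),
                objective=float(t["objective"]),
                rank=int(t["rank"]),
            )
        )
    if not out:
        raise FormatError(f"{path}: no topologies in report")
    return out


def export_restraints(
    topology: SheetTopology, path, config: ModelConfig | None = None
) -> int:
    """Write contacted residue pairs as Cα–Cα distance restraints (TSV).

    Each realized residue pair becomes one row (res_k, res_l, lower_Å,
    upper_Å) with the configured hydrogen-bond distance window — the input
    a torsion-angle-dynamics refinement stage consumes.  Returns the number
    of rows written.
    """
    config = config or ModelConfig()
    n = 0
    with open(path, "w") as fh:
        fh.write("# res_k\tres_l\tlower_A\tupper_A\n")
        for c in topology.contacts:
            for k, l in c.residue_pairs:
                fh.write(
                    f"{k}\t{l}\t{config.restraint_lower:.2f}\t{config.restraint_upper:.2f}\n"
                )
                n += 1
    return n
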