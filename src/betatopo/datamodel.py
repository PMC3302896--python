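"""Core domain types for β-sheet topology prediction.

Coordinates are 1-based and inclusive throughout (DSSP convention).  A
*strand* is a maximal run of residues in extended conformation; a *contact*
is a hydrogen-bonded pairing of two strands at a fixed register (offset) and
orientation; a *topology* is a set of contacts partitioning the strands into
sheets.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Orientation",
    "Strand",
    "ProteinRecord",
    "StrandContact",
    "SheetTopology",
    "ModelConfig",
    "ValidationError",
    "FormatError",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Default hydrophobic residue set (aliphatic + aromatic + C).
HYDROPHOBIC = frozenset("AVLIMFWCY")


class ValidationError(ValueError):
    """Input violates a domain invariant (overlapping strands, bad range...)."""


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class Orientation(str, enum.Enum):
    ANTIPARALLEL = "antiparallel"
    PARALLEL = "parallel"

    @property
    def short(self) -> str:
        return "A" if self is Orientation.ANTIPARALLEL else "P"

    @classmethod
    def from_str(cls, s: str) -> "Orientation":
        s = s.strip().lower()
        if s in ("a", "antiparallel", "anti"):
            return cls.ANTIPARALLEL
        if s in ("p", "parallel"):
            return cls.PARALLEL
        raise ValueError(f"unknown orientation: {s!r}")


@dataclass(frozen=True)
class Strand:
    """One β-strand segment.

    ``index`` is the 1-based ordinal of the strand along the sequence,
    ``start``/``end`` are 1-based inclusive residue positions.
    """

    index: int
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"strand {self.index}: start {self.start} > end {self.end}"
            )
        if len(self.residues) != self.length:
            raise ValidationError(
                f"strand {self.index}: residues {self.residues!r} do not span "
                f"[{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        """Global residue positions covered (1-based, inclusive)."""
        return range(self.start, self.end + 1)

    def hydrophobic_count(self, hydrophobic: frozenset = HYDROPHOBIC) -> int:
        return sum(1 for r in self.residues if r in hydrophobic)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus its strand decomposition.

    ``f_beta``/``f_alpha`` are the fractions of residues in strands and
    helices; they feed the hydrogen-bond budget of the optimization model.
    """

    id: str
    sequence: str
    strands: tuple[Strand, ...] = ()
    helix_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for s in self.strands:
            if s.start <= prev_end:
                raise ValidationError(
                    f"protein {self.id}: strand {s.index} overlaps or is out of "
                    f"order (starts at {s.start}, previous ends at {prev_end})"
                )
            if s.end > len(self.sequence):
                raise ValidationError(
                    f"protein {self.id}: strand {s.index} ends at {s.end}, "
                    f"beyond sequence length {len(self.sequence)}"
                )
            seq_slice = self.sequence[s.start - 1 : s.end]
            if seq_slice != s.residues:
                raise ValidationError(
                    f"protein {self.id}: strand {s.index} residues "
                    f"{s.residues!r} do not match sequence slice {seq_slice!r}"
                )
            prev_end = s.end

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def f_beta(self) -> float:
        if not self.sequence:
            return 0.0
        return sum(s.length for s in self.strands) / self.n_residues

    @property
    def f_alpha(self) -> float:
        if not self.sequence:
            return 0.0
        return sum(e - b + 1 for b, e in self.helix_segments) / self.n_residues

    @property
    def n_beta_residues(self) -> int:
        return sum(s.length for s in self.strands)

    def strand(self, index: int) -> Strand:
        return self.strands[index - 1]

    def with_strands(self, strands: Sequence[Strand]) -> "ProteinRecord":
        return replace(self, strands=tuple(strands))


@dataclass(frozen=True)
class StrandContact:
    """An oriented contact between strands ``i < j`` at a fixed register.

    ``residue_pairs`` lists the hydrogen-bonded residue pairs (global 1-based
    positions, smaller first) realized by the best gapless alignment of the
    two strands in this orientation.
    """

    i: int
    j: int
    orientation: Orientation
    offset: int
    residue_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValidationError(f"contact requires i < j, got ({self.i}, {self.j})")
        for k, l in self.residue_pairs:
            if k >= l:
                raise ValidationError(f"residue pair ({k}, {l}) requires k < l")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)

    @property
    def n_pairs(self) -> int:
        return len(self.residue_pairs)

    def interval_on(self, strand_index: int) -> tuple[int, int] | None:
        """Global residue interval this contact occupies on one of its strands."""
        if strand_index == self.i:
            ks = [k for k, _ in self.residue_pairs]
        elif strand_index == self.j:
            ks = [l for _, l in self.residue_pairs]
        else:
            return None
        if not ks:
            return None
        return (min(ks), max(ks))


@dataclass(frozen=True)
class SheetTopology:
    """A set of oriented strand contacts forming one or more β-sheets."""

    contacts: tuple[StrandContact, ...]
    objective: float = 0.0
    rank: int = 0

    @property
    def contact_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(c.pair for c in self.contacts)

    @property
    def oriented_pairs(self) -> frozenset[tuple[int, int, str]]:
        return frozenset((c.i, c.j, c.orientation.short) for c in self.contacts)

    def degree(self, strand_index: int) -> int:
        return sum(1 for c in self.contacts if strand_index in c.pair)

    def contacts_of(self, strand_index: int) -> list[StrandContact]:
        return [c for c in self.contacts if strand_index in c.pair]

    def sheets(self, n_strands: int) -> list[list[int]]:
        """Partition of strands into sheets (connected components)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, n_strands + 1))
        g.add_edges_from(c.pair for c in self.contacts)
        return sorted(sorted(comp) for comp in nx.connected_components(g))


def _default_locality_weights() -> dict[int, float]:
    # Down-weight sequence-local pairings: database-derived pair potentials
    # over-represent local contacts, so separation-1 scores are shrunk.
    return {1: 0.9, 2: 1.0}


@dataclass
class ModelConfig:
    """All tunable parameters of the scoring and optimization model.

    Defaults encode the published model: at most 3 contacts per strand, at
    least 1, at most N−1 in total; a hydrogen-bond budget of
    0.638·(β-residues) ± 15%; non-local contacts at sequence separation ≥ 3
    require an enabling neighbor contact; one terminal-strand set per five
    strands.
    """

    #: multiplicative locality correction per sequence separation; separations
    #: beyond the largest key use the value at the largest key.
    locality_weights: dict[int, float] = field(default_factory=_default_locality_weights)
    max_contacts_per_strand: int = 3
    #: lower/upper residue-contact budget per strand as a function of length L
    #: (kappa values are additive/multiplicative slack: lo = max(1, L - lo_slack),
    #: hi = hi_factor * L).
    residue_budget_lo_slack: int = 2
    residue_budget_hi_factor: float = 2.0
    #: minimum |j - i| for a contact to count as non-local.
    nonlocal_threshold: int = 3
    #: strands shorter than this are skipped when resolving sequence neighbors.
    min_neighbor_length: int = 4
    hbond_beta_coeff: float = 0.638
    hbond_tolerance: float = 0.15
    hydrophobic_set: frozenset = HYDROPHOBIC
    terminal_set_stride: int = 5
    #: apply the edge/neighbor cap of 3-contact strands to both orientations
    #: ("both") or antiparallel contacts only ("antiparallel").
    edge_rule_orientations: str = "both"
    #: minimum aligned pairs for a strand-pair alignment to be considered.
    min_overlap: int = 2
    #: minimum strand length retained by parsers (shorter runs become coil).
    min_strand_length: int = 2
    #: number of ranked topologies requested.
    K: int = 25
    solver_time_limit: float | None = None
    solver_gap: float = 0.0
    random_seed: int = 0
    #: distance window (Å) used when exporting H-bond restraints.
    restraint_lower: float = 4.2
    restraint_upper: float = 5.5

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.locality_weights.values()):
            raise ValidationError("locality weights must be positive")
        if not (0 < self.hbond_tolerance < 1):
            raise ValidationError("hbond_tolerance must lie in (0, 1)")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if isinstance(self.hydrophobic_set, (set, str, list, tuple)):
            self.hydrophobic_set = frozenset(self.hydrophobic_set)

    def locality_weight(self, separation: int) -> float:
        if not self.locality_weights:
            return 1.0
        d_max = max(self.locality_weights)
        return self.locality_weights[min(separation, d_max)]

    def residue_budget(self, length: int) -> tuple[int, int]:
        lo = max(1, length - self.residue_budget_lo_slack)
        hi = int(round(self.residue_budget_hi_factor * length))
        return lo, hi

    def hbond_bounds(self, n_beta_residues: int) -> tuple[int, int]:
        """Integer bounds on the total number of strand H-bond units."""
        import math

        t = self.hbond_beta_coeff * n_beta_residues
        lo = math.ceil((1.0 - self.hbond_tolerance) * t)
        hi = math.floor((1.0 + self.hbond_tolerance) * t)
        if lo > hi:  # tiny proteins: interval empty after rounding
            import warnings

            nearest = int(round(t))
            warnings.warn(
                f"H-bond budget interval empty after rounding (T={t:.3f}); "
                f"widened to [{nearest}, {nearest}]",
                stacklevel=2,
            )
            lo = hi = nearest
        return lo, hi

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hydrophobic_set"] = "".join(sorted(self.hydrophobic_set))
        d["locality_weights"] = {int(k): float(v) for k, v in self.locality_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        if "hydrophobic_set" in d:
            d["hydrophobic_set"] = frozenset(d["hydrophobic_set"])
        if "locality_weights" in d:
            d["locality_weights"] = {int(k): float(v) for k, v in d["locality_weights"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def strands_from_intervals(
    sequence: str, intervals: Iterable[tuple[int, int]]
) -> tuple[Strand, ...]:
    """Build Strand objects from (start, end) intervals, re-indexed by position."""
    ordered = sorted(intervals)
    out = []
    for idx, (b, e) in enumerate(ordered, start=1):
        if b < 1 or e > len(sequence):
            raise ValidationError(
                f"strand interval ({b}, {e}) outside sequence [1, {len(sequence)}]"
            )
        out.append(Strand(index=idx, start=b, end=e, residues=sequence[b - 1 : e]))
    return tuple(out)
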