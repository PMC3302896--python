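"""Assessment of predicted topologies against a native reference.

Contacts are scored at the strand-pair level over all C(N, 2) unordered
pairs: precision = TP/(TP+FP), recall = TP/(TP+FN), and the Matthews
correlation coefficient.  The default mode ignores orientation when
deciding whether a predicted pair is correct; a strict mode additionally
requires the orientation to match (a right pair in the wrong orientation
then counts as both a false positive and a false negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Iterable, Sequence

from .datamodel import SheetTopology, Strand, ValidationError

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "metrics",
    "weighted_average",
    "best_of_top_k",
    "map_strands",
    "aligned_pair_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    mcc: float
    #: names of quantities whose denominator was zero (reported as 0 by convention)
    degenerate: tuple[str, ...] = ()


def _pair_set(t, oriented: bool):
    if isinstance(t, SheetTopology):
        return set(t.oriented_pairs) if oriented else set(t.contact_pairs)
    out = set()
    for item in t:
        if oriented:
            if len(item) != 3:
                raise ValidationError(
                    "orientation-strict mode needs (i, j, orientation) triples"
                )
            out.add((item[0], item[1], str(item[2])[0].upper()))
        else:
            out.add((item[0], item[1]))
    return out


def confusion(
    predicted,
    native,
    n_strands: int,
    mode: str = "pair",
) -> ConfusionCounts:
    """Strand-pair confusion counts over all C(N, 2) pairs.

    ``mode`` is "pair" (orientation-agnostic) or "pair+orientation".
    """
    if mode not in ("pair", "pair+orientation"):
        raise ValueError(f"unknown confusion mode {mode!r}")
    oriented = mode == "pair+orientation"
    pred = _pair_set(predicted, oriented)
    nat = _pair_set(native, oriented)
    for s in (pred, nat):
        for item in s:
            if not (1 <= item[0] < item[1] <= n_strands):
                raise ValidationError(
                    f"contact {item} outside strand set 1..{n_strands}; "
                    f"map strands first (map_strands) if the sets differ"
                )
    tp = fp = tn = fn = 0
    for i, j in combinations(range(1, n_strands + 1), 2):
        if oriented:
            p_or = {o for (a, b, o) in pred if (a, b) == (i, j)}
            n_or = {o for (a, b, o) in nat if (a, b) == (i, j)}
            if p_or and n_or:
                if p_or & n_or:
                    tp += 1
                else:  # right pair, wrong orientation
                    fp += 1
                    fn += 1
            elif p_or:
                fp += 1
            elif n_or:
                fn += 1
            else:
                tn += 1
        else:
            p = (i, j) in pred
            q = (i, j) in nat
            tp += p and q
            fp += p and not q
            fn += q and not p
            tn += not p and not q
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall and MCC with zero-denominator conventions.

    Precision/recall are 0 when their denominator is 0; the MCC is 0 when
    any factor under the root vanishes.  Degenerate quantities are flagged.
    """
    degenerate = []
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, _ = 0.0, degenerate.append("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, _ = 0.0, degenerate.append("recall")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / sqrt(denom)
    else:
        mcc, _ = 0.0, degenerate.append("mcc")
    return Metrics(
        precision=precision, recall=recall, mcc=mcc, degenerate=tuple(degenerate)
    )


def weighted_average(per_protein: Iterable[tuple[int, float]]) -> float:
    """Weighted average of a per-protein metric over strand-count bins.

    ``per_protein`` yields (n_strands, metric_value) per protein; bins are
    averaged and re-weighted by bin size, which reduces to the plain mean
    over proteins.
    """
    per_protein = list(per_protein)
    if not per_protein:
        raise ValidationError("weighted_average needs at least one protein")
    bins: dict[int, list[float]] = {}
    for s, v in per_protein:
        bins.setdefault(s, []).append(v)
    num = sum(sum(vs) / len(vs) * len(vs) for vs in bins.values())
    den = sum(len(vs) for vs in bins.values())
    return num / den


def best_of_top_k(
    ranked: Sequence[SheetTopology],
    native,
    k: int,
    n_strands: int,
    mode: str = "pair",
) -> Metrics:
    """Metrics of the best topology among ranks 1..k.

    "Best" maximizes MCC, then precision, then prefers the lower rank, so
    the result is non-decreasing in k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    best: tuple | None = None
    best_metrics: Metrics | None = None
    for t in ranked[:k]:
        m = metrics(confusion(t, native, n_strands, mode))
        key = (m.mcc, m.precision, -t.rank)
        if best is None or key > best:
            best = key
            best_metrics = m
    if best_metrics is None:
        raise ValidationError("best_of_top_k needs at least one ranked topology")
    return best_metrics


def map_strands(
    predicted_strands: Sequence[Strand], native_strands: Sequence[Strand]
) -> dict[int, int]:
    """Greedy one-to-one map predicted→native by maximum residue overlap.

    Pairs with zero overlap are never mapped; unmapped strands on either
    side are excluded from evaluation.
    """

    def overlap(a: Strand, b: Strand) -> int:
        return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)

    candidates = sorted(
        (
            (overlap(p, q), p.index, q.index)
            for p in predicted_strands
            for q in native_strands
            if overlap(p, q) >= 1
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_p: set[int] = set()
    used_n: set[int] = set()
    mapping: dict[int, int] = {}
    for _ov, pi, ni in candidates:
        if pi in used_p or ni in used_n:
            continue
        mapping[pi] = ni
        used_p.add(pi)
        used_n.add(ni)
    return mapping


def aligned_pair_accuracy(
    predicted: SheetTopology,
    native_pairs: dict[tuple[int, int], set[tuple[int, int]]],
) -> float | None:
    """Fraction of predicted residue pairs that match the native register.

    Only contacts whose strand pair is correctly predicted (present in
    ``native_pairs``) are scored; None when there are no such contacts.
    """
    n_pred = 0
    n_match = 0
    for c in predicted.contacts:
        if c.pair not in native_pairs:
            continue
        nat = native_pairs[c.pair]
        for p in c.residue_pairs:
            n_pred += 1
            if p in nat:
                n_match += 1
    if n_pred == 0:
        return None
    return n_match / n_pred
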