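import pytest
from hypothesis import given, settings, strategies as st

from betatopo.datamodel import Orientation, SheetTopology, Strand, ValidationError
from betatopo.evaluation import (
    ConfusionCounts,
    aligned_pair_accuracy,
    best_of_top_k,
    confusion,
    map_strands,
    metrics,
    weighted_average,
)

from util_build import build_contact, build_protein, topology

A = Orientation.ANTIPARALLEL
P = Orientation.PARALLEL


def contact_sets(*pairs):
    return list(pairs)


class TestConfusion:
    def test_perfect_prediction(self):
        native = contact_sets((1, 2), (2, 3), (3, 4))
        c = confusion(native, native, 4)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 3)

    def test_empty_prediction(self):
        c = confusion([], contact_sets((1, 2), (2, 3), (3, 4)), 4)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 3, 3)

    def test_disjoint_sets(self):
        c = confusion(
            contact_sets((1, 2), (3, 4)), contact_sets((1, 3), (2, 4)), 4
        )
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 2, 2, 2)

    def test_counts_sum_to_pair_universe(self):
        c = confusion(contact_sets((1, 4), (2, 3)), contact_sets((1, 2)), 5)
        assert c.total == 10  # C(5, 2)

    def test_wrong_orientation_counts_against_in_strict_mode(self):
        pred = [(1, 2, "A")]
        nat = [(1, 2, "P")]
        c = confusion(pred, nat, 3, mode="pair+orientation")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 1, 2)
        # orientation-agnostic default calls the same pair a hit
        c2 = confusion([(1, 2)], [(1, 2)], 3)
        assert c2.tp == 1

    def test_out_of_range_contact_directs_to_mapping(self):
        with pytest.raises(ValidationError, match="map"):
            confusion(contact_sets((1, 7)), contact_sets((1, 2)), 4)


class TestMetrics:
    def test_formula_substitution(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)

    def test_perfect_prediction_saturates(self):
        m = metrics(ConfusionCounts(tp=4, fp=0, tn=2, fn=0))
        assert (m.precision, m.recall, m.mcc) == (1.0, 1.0, 1.0)

    def test_zero_denominator_conventions_flagged(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=6, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.mcc == 0.0
        assert set(m.degenerate) == {"precision", "recall", "mcc"}

    def test_mcc_symmetric_under_swapping_prediction_and_truth(self):
        # swapping prediction and truth transposes fp and fn
        a = metrics(ConfusionCounts(tp=3, fp=2, tn=4, fn=1)).mcc
        b = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2)).mcc
        assert a == pytest.approx(b)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_bounds_hold(self, counts):
        m = metrics(ConfusionCounts(*counts))
        assert 0.0 <= m.precision <= 1.0
        assert 0.0 <= m.recall <= 1.0
        assert -1.0 <= m.mcc <= 1.0


class TestWeightedAverage:
    def test_two_bins(self):
        # {s=3: avg 1.0 of 1 protein}, {s=4: avg 0.5 of 3} -> 0.625
        data = [(3, 1.0), (4, 0.5), (4, 0.5), (4, 0.5)]
        assert weighted_average(data) == pytest.approx(0.625)

    def test_single_protein_identity(self):
        assert weighted_average([(5, 0.7)]) == pytest.approx(0.7)

    def test_equals_plain_mean(self):
        import numpy as np

        rng = np.random.default_rng(2)
        data = [(int(rng.integers(3, 9)), float(rng.random())) for _ in range(40)]
        assert weighted_average(data) == pytest.approx(
            sum(v for _s, v in data) / len(data)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            weighted_average([])


class TestBestOfTopK:
    def _ranked(self):
        p = build_protein([5, 5, 5, 5])
        t_wrong = SheetTopology(
            contacts=topology(
                build_contact(p, 1, 3), build_contact(p, 2, 4), build_contact(p, 1, 2)
            ).contacts,
            rank=1,
        )
        t_right = SheetTopology(
            contacts=topology(
                build_contact(p, 1, 2), build_contact(p, 2, 3), build_contact(p, 3, 4)
            ).contacts,
            rank=3,
        )
        t_mid = SheetTopology(
            contacts=topology(build_contact(p, 1, 2), build_contact(p, 3, 4)).contacts,
            rank=2,
        )
        return [t_wrong, t_mid, t_right], t_right

    def test_native_at_rank_three(self):
        ranked, native = self._ranked()
        m = best_of_top_k(ranked, native, k=3, n_strands=4)
        assert (m.precision, m.recall, m.mcc) == (1.0, 1.0, 1.0)

    def test_k1_uses_rank_one(self):
        ranked, native = self._ranked()
        m1 = best_of_top_k(ranked, native, k=1, n_strands=4)
        direct = metrics(confusion(ranked[0], native, 4))
        assert m1 == direct

    def test_monotone_in_k(self):
        ranked, native = self._ranked()
        vals = [
            best_of_top_k(ranked, native, k, n_strands=4).mcc
            for k in range(1, len(ranked) + 1)
        ]
        assert vals == sorted(vals)


class TestMapStrands:
    def _strands(self, intervals, seq_len=30):
        seq = "V" * seq_len
        return [
            Strand(index=i, start=b, end=e, residues=seq[b - 1 : e])
            for i, (b, e) in enumerate(intervals, start=1)
        ]

    def test_identity_mapping(self):
        s = self._strands([(2, 6), (10, 14)])
        assert map_strands(s, s) == {1: 1, 2: 2}

    def test_maps_to_larger_overlap(self):
        pred = self._strands([(4, 9)])
        native = self._strands([(3, 7), (10, 14)])
        assert map_strands(pred, native) == {1: 1}

    def test_one_to_one_leaves_weaker_overlap_unmapped(self):
        pred = self._strands([(3, 7), (6, 9)])
        native = self._strands([(3, 8)])
        mapping = map_strands(pred, native)
        assert mapping == {1: 1}  # 5-residue overlap beats 3

    def test_zero_overlap_never_mapped(self):
        pred = self._strands([(1, 3)])
        native = self._strands([(10, 12)])
        assert map_strands(pred, native) == {}


class TestAlignedPairAccuracy:
    def test_identity_register(self, fx4):
        assert aligned_pair_accuracy(fx4.planted, fx4.native_pairs) == 1.0

    def test_shifted_register_scores_zero(self):
        p = build_protein([5, 5, 5])
        pred = topology(build_contact(p, 1, 2, P, offset=1), build_contact(p, 2, 3, P))
        native = topology(build_contact(p, 1, 2, P, offset=0), build_contact(p, 2, 3, P))
        native_pairs = {c.pair: set(c.residue_pairs) for c in native.contacts}
        acc = aligned_pair_accuracy(pred, native_pairs)
        # (1,2) fully shifted: 0/4; (2,3) exact: 5/5
        assert acc == pytest.approx(5 / 9)

    def test_no_common_strand_pairs_is_undefined(self):
        p = build_protein([5, 5, 5])
        pred = topology(build_contact(p, 1, 2))
        assert aligned_pair_accuracy(pred, {(2, 3): set()}) is None
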