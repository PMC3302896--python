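import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from betatopo.datamodel import ModelConfig, Orientation, Strand, ValidationError
from betatopo.scoring import (
    PotentialTable,
    align_pair,
    default_potential_table,
    locality_correct,
    score_all_pairs,
)

from util_build import build_protein


def table_from(scores: dict[tuple[str, str], float], letters="AV") -> PotentialTable:
    df = pd.DataFrame(0.0, index=list(letters), columns=list(letters))
    for (a, b), v in scores.items():
        df.at[a, b] = v
        df.at[b, a] = v
    return PotentialTable(df, name="test")


def oracle_best(si, sj, orientation, table, min_overlap=2):
    """Independent exhaustive-offset scorer: all shifts, full window each."""
    best = None
    li, lj = si.length, sj.length
    for shift in range(-lj - 1, li + 2):
        pairs = []
        for a in range(li):
            if orientation is Orientation.PARALLEL:
                b = a - shift
            else:
                b = lj - 1 - a + shift
            if 0 <= b < lj:
                pairs.append((a, b))
        if len(pairs) < min_overlap:
            continue
        score = sum(table.score(si.residues[a], sj.residues[b]) for a, b in pairs)
        if best is None or score > best:
            best = score
    return best


def strand(idx: int, residues: str, start: int = None) -> Strand:
    start = start if start is not None else idx * 20
    return Strand(index=idx, start=start, end=start + len(residues) - 1, residues=residues)


class TestAlignPair:
    def test_identical_dimers_parallel(self):
        t = table_from({("V", "V"): 1.0})
        aln = align_pair(strand(1, "VV"), strand(2, "VV"), Orientation.PARALLEL, t)
        assert aln.offset == 0
        assert aln.raw_score == pytest.approx(2.0)
        assert aln.n_pairs == 2

    def test_antiparallel_matches_exhaustive_oracle(self):
        t = table_from({("V", "V"): 2.0, ("A", "A"): 2.0, ("A", "V"): 0.0})
        si, sj = strand(1, "AV"), strand(2, "VA")
        aln = align_pair(si, sj, Orientation.ANTIPARALLEL, t)
        assert aln.raw_score == pytest.approx(
            oracle_best(si, sj, Orientation.ANTIPARALLEL, t)
        )
        assert aln.raw_score == pytest.approx(4.0)  # A-A and V-V both align

    def test_too_short_for_min_overlap(self):
        t = table_from({("V", "V"): 1.0})
        assert align_pair(strand(1, "V"), strand(2, "VVV"), Orientation.PARALLEL, t) is None

    def test_tie_broken_by_smallest_absolute_offset(self):
        # homopolymer pair: every full-overlap register ties; |offset| breaks it
        t = table_from({("V", "V"): 1.0})
        aln = align_pair(strand(1, "VVVV"), strand(2, "VV"), Orientation.PARALLEL, t)
        assert aln.offset == 0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        st.text(alphabet="AVDC", min_size=2, max_size=8),
        st.text(alphabet="AVDC", min_size=2, max_size=8),
        st.sampled_from(list(Orientation)),
        st.integers(0, 10**6),
    )
    def test_property_equals_offset_enumeration_oracle(self, ri, rj, orientation, seed):
        rng = np.random.default_rng(seed)
        letters = list("AVDC")
        vals = rng.uniform(-1, 1, (4, 4))
        df = pd.DataFrame((vals + vals.T) / 2, index=letters, columns=letters)
        t = PotentialTable(df)
        si, sj = strand(1, ri), strand(2, rj)
        aln = align_pair(si, sj, orientation, t)
        expected = oracle_best(si, sj, orientation, t)
        if expected is None:
            assert aln is None
        else:
            assert aln.raw_score == pytest.approx(expected)

    def test_scale_equivariance(self):
        t = table_from({("V", "V"): 1.0, ("A", "V"): -0.5, ("A", "A"): 0.25})
        si, sj = strand(1, "AVVA"), strand(2, "VAVV")
        for o in Orientation:
            a1 = align_pair(si, sj, o, t)
            a3 = align_pair(si, sj, o, t.scaled(3.0))
            assert a3.raw_score == pytest.approx(3.0 * a1.raw_score)
            assert a3.pairs == a1.pairs


class TestLocalityCorrection:
    def test_identity_weight_far_separation(self):
        cfg = ModelConfig(locality_weights={1: 1.0, 2: 1.0})
        assert locality_correct(10.0, 1, 6, cfg) == pytest.approx(10.0)

    def test_local_downweight(self):
        assert locality_correct(10.0, 3, 4, ModelConfig()) == pytest.approx(9.0)

    def test_monotone_in_separation_for_positive_raw(self):
        cfg = ModelConfig()
        assert locality_correct(10.0, 1, 2, cfg) <= locality_correct(10.0, 1, 4, cfg)

    def test_requires_ordered_indices(self):
        with pytest.raises(ValidationError):
            locality_correct(1.0, 4, 2, ModelConfig())


class TestScoreAllPairs:
    def test_pair_and_orientation_counts(self):
        protein = build_protein([4, 4, 4])
        sp = score_all_pairs(protein, default_potential_table())
        assert len(sp) <= 6
        assert set(sp.pairs()) == {(1, 2), (1, 3), (2, 3)}

    def test_symmetric_access(self):
        protein = build_protein([4, 5, 6])
        sp = score_all_pairs(protein, default_potential_table())
        for o in Orientation:
            assert sp.get(2, 1, o) is sp.get(1, 2, o)

    def test_refuses_fewer_than_three_strands(self):
        protein = build_protein([4, 4])
        with pytest.raises(ValidationError, match="at least 3"):
            score_all_pairs(protein, default_potential_table())

    def test_every_entry_is_offset_optimal(self, fx4):
        for (i, j, o), aln in fx4.scored.items():
            si, sj = fx4.protein.strand(i), fx4.protein.strand(j)
            assert aln.raw_score == pytest.approx(oracle_best(si, sj, o, fx4.table))


class TestPotentialTable:
    def test_default_table_symmetric_finite(self):
        t = default_potential_table()
        m = t.scores.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all(np.isfinite(m))
        assert t.score("X", "V") == 0.0

    def test_asymmetric_table_rejected(self):
        df = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["A", "V"], columns=["A", "V"])
        with pytest.raises(ValidationError, match="symmetric"):
            PotentialTable(df)

    def test_tsv_round_trip(self, tmp_path):
        t = default_potential_table()
        t.to_tsv(tmp_path / "t.tsv")
        back = PotentialTable.from_tsv(tmp_path / "t.tsv")
        assert np.allclose(back.scores.to_numpy(), t.scores.to_numpy())
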