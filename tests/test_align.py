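"""Affine-gap global alignment, gap-excluded identity, all-vs-all contract."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribobound import (
    AlignmentResult,
    ScoringScheme,
    SequenceRecord,
    StrainDataset,
    all_vs_all_identity,
    global_align,
    pair_count,
    percent_identity,
)
from ribobound.align import score_from_aligned

from conftest import make_taxonomy
from oracles import brute_force_best_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestGlobalAlign:
    def test_identical_sequences(self):
        r = global_align("ACGTA", "ACGTA")
        assert r.score == 10.0
        assert r.n_gap_columns == 0
        assert r.identity_pct == 100.0

    def test_single_gap_optimum(self):
        # ACGT vs AGT: match 2, open one gap -10, match 2, match 2
        r = global_align("ACGT", "AGT")
        assert r.score == -4.0
        assert (r.aligned_a, r.aligned_b) == ("ACGT", "A-GT")
        assert r.identity_pct == 100.0  # 3 matches over 3 gapless columns

    def test_all_mismatch_beats_gapping(self):
        r = global_align("AAAA", "TTTT")
        assert r.score == -4.0
        assert r.identity_pct == 0.0
        assert r.n_gap_columns == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gap_run_cost_convention(self):
        # a run of k gap characters costs open + (k-1)*extend
        s = ScoringScheme()
        assert s.gap_run_cost(1) == -10.0
        assert s.gap_run_cost(4) == -11.5

    @given(dna, dna)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        """DP optimum equals the brute-force maximum over all alignments."""
        r = global_align(a, b)
        assert r.score == pytest.approx(brute_force_best_score(a, b), abs=1e-9)

    @given(dna, dna)
    def test_returned_alignment_attains_reported_score(self, a, b):
        r = global_align(a, b)
        assert score_from_aligned(r.aligned_a, r.aligned_b) == pytest.approx(
            r.score, abs=1e-9
        )
        # degapping recovers the inputs
        assert r.aligned_a.replace("-", "") == a
        assert r.aligned_b.replace("-", "") == b

    @given(dna, dna)
    def test_symmetry(self, a, b):
        ra, rb = global_align(a, b), global_align(b, a)
        assert ra.score == pytest.approx(rb.score, abs=1e-9)
        # co-optimal alignments may differ between orders; identity must
        # agree closely even then
        if not (math.isnan(ra.identity_pct) or math.isnan(rb.identity_pct)):
            assert abs(ra.identity_pct - rb.identity_pct) <= 0.5

    def test_self_identity_is_exactly_100(self):
        rng = random.Random(5)
        for _ in range(10):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 300)))
            assert global_align(s, s).identity_pct == 100.0

    def test_ambiguity_codes_match_only_on_equality(self):
        r = global_align("ANNA", "ANCA")
        # N==N is a match; N vs C is a mismatch
        assert (r.n_match, r.n_mismatch) == (3, 1)

    @settings(max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_reference_aligner(self, seed):
        """Scores match Biopython's PairwiseAligner on gap-inducing pairs."""
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="global", match_score=2, mismatch_score=-1,
            open_gap_score=-10, extend_gap_score=-0.5,
        )
        rng = random.Random(seed)
        base = [rng.choice("ACGT") for _ in range(rng.randint(60, 160))]
        a = list(base)
        b = list(base)
        for s in (a, b):
            for _ in range(rng.randint(0, 3)):  # indels to force gap columns
                pos = rng.randrange(len(s))
                if rng.random() < 0.5:
                    del s[pos : pos + rng.randint(1, 5)]
                else:
                    s[pos:pos] = rng.choice("ACGT") * rng.randint(1, 5)
            for _ in range(rng.randint(0, 20)):  # substitutions
                pos = rng.randrange(len(s))
                s[pos] = rng.choice("ACGT")
        a, b = "".join(a), "".join(b)
        if not a or not b:
            return
        assert global_align(a, b).score == pytest.approx(
            aligner.score(a, b), abs=1e-9
        )


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "aligned_a,aligned_b,expected",
        [
            ("AC-GT", "ACTGT", 100.0),   # 4 matches / 4 gapless columns
            ("ACGT", "AGGT", 75.0),      # 3 matches / 4 columns, no gaps
            ("AAGT", "A-CT", 200.0 / 3), # 2 matches / 3 gapless columns
        ],
    )
    def test_gap_excluded_formula(self, aligned_a, aligned_b, expected):
        aln = AlignmentResult.from_aligned(aligned_a, aligned_b)
        assert percent_identity(aln) == pytest.approx(expected, abs=1e-9)

    def test_two_decimal_rendering_of_thirds(self):
        aln = AlignmentResult.from_aligned("AAGT", "A-CT")
        assert round(percent_identity(aln), 2) == 66.67

    def test_all_gap_columns_is_undefined(self):
        aln = AlignmentResult(
            aligned_a="A-", aligned_b="-A", score=-20.0,
            n_match=0, n_mismatch=0, n_gap_columns=2, identity_pct=math.nan,
        )
        assert math.isnan(percent_identity(aln))

    def test_both_gaps_in_one_column_rejected(self):
        with pytest.raises(ValueError):
            AlignmentResult.from_aligned("A-G", "A-G")


def tiny_dataset(seqs: dict[str, str]) -> StrainDataset:
    return StrainDataset(
        sequences={k: SequenceRecord(k, v) for k, v in seqs.items()},
        taxonomy={k: make_taxonomy(k) for k in seqs},
    )


class TestAllVsAll:
    SEQS = {
        "a": "ACGTACGTACGTACGT",
        "b": "ACGTACGTACGAACGT",
        "c": "TTGTACGTACGTACGA",
        "d": "ACGAACGTACGTTCGT",
    }

    def test_three_sequences_three_pairs(self):
        ds = tiny_dataset({k: self.SEQS[k] for k in ("a", "b", "c")})
        m = all_vs_all_identity(ds, n_chunks=2)
        m.validate()
        assert pair_count(len(m.ids)) == 3
        assert m.get("a", "b") == m.get("b", "a")

    def test_chunking_does_not_change_results(self):
        ds = tiny_dataset(self.SEQS)
        m1 = all_vs_all_identity(ds, n_chunks=1)
        m7 = all_vs_all_identity(ds, n_chunks=7)
        assert np.array_equal(m1.values, m7.values)  # bit-for-bit

    def test_worker_count_does_not_change_results(self):
        ds = tiny_dataset(self.SEQS)
        m1 = all_vs_all_identity(ds, n_chunks=5, n_workers=1)
        m2 = all_vs_all_identity(ds, n_chunks=5, n_workers=3)
        assert np.array_equal(m1.values, m2.values)

    def test_matrix_matches_single_alignments(self):
        ds = tiny_dataset(self.SEQS)
        m = all_vs_all_identity(ds, n_chunks=3)
        for ida, idb, ident in m.iter_pairs():
            direct = global_align(self.SEQS[ida], self.SEQS[idb]).identity_pct
            assert ident == direct

    def test_bad_parameters_rejected(self):
        ds = tiny_dataset(self.SEQS)
        with pytest.raises(ValueError):
            all_vs_all_identity(ds, n_chunks=0)
        with pytest.raises(ValueError):
            all_vs_all_identity(tiny_dataset({"a": "ACGT"}))

    def test_pairs_tsv_round_trip(self, tmp_path):
        ds = tiny_dataset(self.SEQS)
        m = all_vs_all_identity(ds, n_chunks=2)
        p = tmp_path / "pairs.tsv"
        m.write_pairs_tsv(p)
        from ribobound import IdentityMatrix

        back = IdentityMatrix.read_pairs_tsv(p)
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values, atol=5e-5)  # 4-decimal file


class TestScoringScheme:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=1, mismatch=1)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1, gap_extend=-2)
        with pytest.raises(ValueError):
            ScoringScheme(gap_extend=0.5)


def test_pair_count_arithmetic():
    assert pair_count(2) == 1
    assert pair_count(3) == 3
    with pytest.raises(ValueError):
        pair_count(-1)
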