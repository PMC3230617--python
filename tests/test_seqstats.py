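import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locustmeth import (
    ALL_DINUCLEOTIDES,
    CloneCensus,
    SequenceRecord,
    all_dinucleotide_profiles,
    clone_census_percentages,
    count_dinucleotides,
    dinucleotide_oe,
    oe_profile,
    pairwise_identity,
)
from locustmeth.io import normalize_residues


def naive_counts(residues):
    """Window-by-window enumeration oracle for dinucleotide counting."""
    mono = {b: 0 for b in "ACGT"}
    for ch in residues:
        if ch in mono:
            mono[ch] += 1
    di = {xy: 0 for xy in ALL_DINUCLEOTIDES}
    W = 0
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        if a in "ACGT" and b in "ACGT":
            di[a + b] += 1
            W += 1
    return mono, di, W


class TestCountDinucleotides:
    def test_cg_repeat_hand_enumeration(self):
        c = count_dinucleotides(SequenceRecord("g", "CGCGCGCG"))
        assert c.mono == {"A": 0, "C": 4, "G": 4, "T": 0}
        assert c.L_eff == 8
        assert c.di["CG"] == 4 and c.di["GC"] == 3
        assert c.W == 7

    def test_n_spanning_windows_excluded(self):
        c = count_dinucleotides(SequenceRecord("g", "CGNNCG"))
        assert c.mono["C"] == 2 and c.mono["G"] == 2
        assert c.L_eff == 4
        assert c.di["CG"] == 2
        assert c.W == 2

    def test_degenerate_all_n(self):
        c = count_dinucleotides(SequenceRecord("g", "N"))
        assert c.L_eff == 0 and c.W == 0
        assert sum(c.di.values()) == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=200),
    )
    def test_matches_naive_enumeration(self, residues):
        rec = SequenceRecord("g", residues)
        c = count_dinucleotides(rec)
        mono, di, W = naive_counts(residues)
        assert c.mono == mono
        assert c.di == di
        assert c.W == W
        assert sum(c.di.values()) == c.W
        assert c.W <= rec.length - 1 if rec.length > 1 else c.W == 0
        assert c.L_eff <= rec.length


class TestDinucleotideOE:
    def test_cg_repeat_hand_arithmetic(self):
        c = count_dinucleotides(SequenceRecord("g", "CGCGCGCG"))
        rec = dinucleotide_oe(c, "CG")
        assert rec.defined
        assert rec.oe == pytest.approx((4 / 7) / ((4 / 8) * (4 / 8)))

    def test_zero_denominator_undefined(self):
        c = count_dinucleotides(SequenceRecord("g", "ATATATAT"))
        rec = dinucleotide_oe(c, "CG")
        assert not rec.defined
        assert rec.reason == "zero_mono_x"
        assert math.isnan(rec.oe)

    def test_zero_numerator_gives_zero(self):
        # C and G both present but never adjacent as CG
        c = count_dinucleotides(SequenceRecord("g", "GGGGCCCC"))
        rec = dinucleotide_oe(c, "CG")
        assert rec.defined and rec.oe == 0.0

    def test_min_length_filter(self):
        c = count_dinucleotides(SequenceRecord("g", "CGCG"))
        rec = dinucleotide_oe(c, "CG", min_length=100)
        assert rec.reason == "too_short"

    def test_invalid_dinucleotide(self):
        c = count_dinucleotides(SequenceRecord("g", "ACGT"))
        with pytest.raises(ValueError):
            dinucleotide_oe(c, "CN")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=120))
    def test_reverse_complement_invariance_of_cpg(self, residues):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(residues))
        a = dinucleotide_oe(count_dinucleotides(SequenceRecord("f", residues)), "CG")
        b = dinucleotide_oe(count_dinucleotides(SequenceRecord("r", rc)), "CG")
        if a.defined and b.defined:
            assert a.oe == pytest.approx(b.oe)
        else:
            assert a.defined == b.defined

    def test_case_insensitive_after_normalization(self):
        raw = "cgtAcgGNnCgt"
        up, _ = normalize_residues(raw)
        lo, _ = normalize_residues(raw.lower())
        a = dinucleotide_oe(count_dinucleotides(SequenceRecord("a", up)), "CG")
        b = dinucleotide_oe(count_dinucleotides(SequenceRecord("b", lo)), "CG")
        assert a.oe == b.oe

    def test_n_block_insertion_only_drops_spanning_windows(self):
        # inserting an N block between two halves removes only the junction
        # window; O/E recomputed on N-free windows matches hand arithmetic
        left, right = "CGCG", "GCGC"
        joined = SequenceRecord("j", left + "NNN" + right)
        c = count_dinucleotides(joined)
        mono, di, W = naive_counts(joined.residues)
        assert c.W == W == 6  # 3 windows per half
        rec = dinucleotide_oe(c, "CG")
        expected = (di["CG"] / W) / ((mono["C"] / 8) * (mono["G"] / 8))
        assert rec.oe == pytest.approx(expected)


class TestOEProfile:
    def test_all_n_gene_flagged_not_dropped(self):
        recs = [
            SequenceRecord("g1", "CGCGCGCGCG"),
            SequenceRecord("g2", "NNNNN"),
            SequenceRecord("g3", "ACGTACGTAC"),
        ]
        profile = oe_profile(recs, "CG", min_length=2)
        assert len(profile) == 3
        assert [r.defined for r in profile] == [True, False, True]
        assert profile[1].reason in ("too_short", "no_windows")

    def test_matches_per_gene_calls(self, planted_unigenes):
        recs = planted_unigenes[0][:50]
        profile = oe_profile(recs, "CG")
        for rec, out in zip(recs, profile):
            direct = dinucleotide_oe(count_dinucleotides(rec), "CG", min_length=100)
            assert out == direct

    def test_subset_semantics(self):
        recs = [SequenceRecord(f"g{i}", "ACGT" * 30) for i in range(5)]
        sub = oe_profile(recs, "CG", min_length=10, subset=["g3", "g1"])
        assert [r.gene_id for r in sub] == ["g3", "g1"]
        with pytest.raises(KeyError):
            oe_profile(recs, "CG", subset=["missing"])

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            oe_profile([], "CG")


class TestAllDinucleotideProfiles:
    def test_sixteen_keys_and_cg_consistency(self):
        recs = [SequenceRecord(f"g{i}", "ACGTTGCA" * 20) for i in range(4)]
        profiles = all_dinucleotide_profiles(recs, min_length=10)
        assert set(profiles) == set(ALL_DINUCLEOTIDES)
        assert profiles["CG"] == oe_profile(recs, "CG", min_length=10)


class TestPairwiseIdentity:
    def test_identical_ungapped(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == (10, 10, 100.0)

    def test_gap_column_compared_not_identical(self):
        assert pairwise_identity("AC-G", "ACTG") == (3, 4, 75.0)

    def test_double_gap_column_dropped(self):
        assert pairwise_identity("A-CG", "A-CG") == (3, 3, 100.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACG", "AC")

    def test_rounding_to_one_decimal(self):
        # 340/351 = 96.866... -> 96.9
        a = "A" * 340 + "C" * 11
        b = "A" * 340 + "D" * 11
        assert pairwise_identity(a, b) == (340, 351, 96.9)


class TestCloneCensus:
    def test_methyl_enriched_clone_table(self):
        census = CloneCensus({"repetitive": 15, "est": 9, "unknown": 25})
        pct = clone_census_percentages(census)
        assert pct == {"repetitive": 31, "est": 18, "unknown": 51}

    def test_single_category(self):
        assert clone_census_percentages(CloneCensus({"x": 1})) == {"x": 100}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            CloneCensus({"x": 0})
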