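import pytest
from hypothesis import given, strategies as st

from cupep.core import AMINO_ACIDS, Peptide, PeptidePopulation
from cupep.motifs import (build_catalog, cross_condition_compare,
                          generate_windows, normalized_hamming, shared_cores)

aa_text = st.text(alphabet=list(AMINO_ACIDS), min_size=1, max_size=20)


def fixed_len(n):
    return st.text(alphabet=list(AMINO_ACIDS), min_size=n, max_size=n)


class TestGenerateWindows:
    def test_direct_enumeration(self):
        assert generate_windows("ACDEF", 3) == ["ACD", "CDE", "DEF"]

    def test_whole_peptide_window(self):
        assert generate_windows("ACDEF", 5) == ["ACDEF"]

    @given(aa_text, st.integers(1, 20))
    def test_window_count_identity(self, seq, n):
        if n > len(seq):
            with pytest.raises(ValueError):
                generate_windows(seq, n)
        else:
            assert len(generate_windows(seq, n)) == len(seq) - n + 1

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_windows("ACDEF", 0)
        with pytest.raises(ValueError):
            generate_windows("ACDEF", 6)


class TestBuildCatalog:
    def test_hand_count_with_frequency_filter(self):
        pop = PeptidePopulation.from_sequences(["ACDE", "WCDE"])
        cat = build_catalog(pop, 3, min_count=2)
        assert cat.pooled() == {"CDE": 2}

    def test_min_count_one_keeps_all_distinct_windows(self):
        pop = PeptidePopulation.from_sequences(["ACDE", "WCDE"])
        cat = build_catalog(pop, 3, min_count=1)
        assert set(cat.pooled()) == {"ACD", "CDE", "WCD"}

    def test_total_multiplicity_is_sum_of_window_counts(self, random_peptides):
        pop = PeptidePopulation.from_sequences(random_peptides)
        for n in (5, 6, 7):
            cat = build_catalog(pop, n, min_count=1)
            expected = sum(len(s) - n + 1 for s in random_peptides if len(s) >= n)
            assert sum(cat.pooled().values()) == expected

    def test_order_invariance_and_duplication_doubles_counts(self):
        seqs = ["HWPLPPF", "ASEGGHG", "GPHWPLP"]
        pop = PeptidePopulation.from_sequences(seqs)
        rev = PeptidePopulation.from_sequences(seqs[::-1])
        dup = PeptidePopulation.from_sequences(seqs * 2)
        c1 = build_catalog(pop, 5, 1).pooled()
        assert c1 == build_catalog(rev, 5, 1).pooled()
        assert {m: 2 * c for m, c in c1.items()} == build_catalog(dup, 5, 1).pooled()

    def test_provenance_recovers_every_window(self):
        seqs = ["HWPLPPF", "ASEGG"]
        pop = PeptidePopulation.from_sequences(seqs)
        cat = build_catalog(pop, 5, min_count=1)
        for motif, idxs in cat.provenance.items():
            for i in idxs:
                assert motif in seqs[i]

    def test_per_peptide_unique_mode(self):
        pop = PeptidePopulation.from_sequences(["AAAAAA"])
        assert build_catalog(pop, 3, 1).pooled()["AAA"] == 4
        assert build_catalog(pop, 3, 1, per_peptide_unique=True).pooled()["AAA"] == 1


class TestNormalizedHamming:
    @pytest.mark.parametrize("a, b, d", [
        ("AAA", "AAA", 0.0),
        ("AAA", "TTT", 1.0),
        ("HWP", "HWA", 1 / 3),
    ])
    def test_examples(self, a, b, d):
        assert normalized_hamming(a, b) == pytest.approx(d)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            normalized_hamming("AA", "AAA")

    @given(fixed_len(6), fixed_len(6), fixed_len(6))
    def test_metric_axioms(self, a, b, c):
        dab = normalized_hamming(a, b)
        assert dab == normalized_hamming(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= normalized_hamming(a, c) + normalized_hamming(c, b) + 1e-12
        assert 0.0 <= dab <= 1.0


class TestCrossCondition:
    def make_catalog(self):
        peps = (
            [Peptide("HWPLPPFGG", condition="pep_tryp")] * 3
            + [Peptide("KHWPLPPFV", condition="papain")] * 3
            + [Peptide("AAASEGGKK", condition="pep_tryp")] * 2
            + [Peptide("VLASEGGPP", condition="papain")] * 2
        )
        return build_catalog(PeptidePopulation(peps), 5, min_count=1)

    def test_identical_top_motif_reported_first_at_distance_zero(self):
        pairs = cross_condition_compare(self.make_catalog(), top_k=50,
                                        max_distance=0.4)
        assert pairs[0].distance == 0.0
        assert pairs[0].motif_a == pairs[0].motif_b

    def test_max_distance_zero_is_verbatim_sharing(self):
        pairs = cross_condition_compare(self.make_catalog(), top_k=50,
                                        max_distance=0.0)
        assert pairs and all(p.motif_a == p.motif_b for p in pairs)
        shared = {p.motif_a for p in pairs}
        assert "ASEGG" in shared and "HWPLP" in shared

    def test_single_condition_rejected(self):
        pop = PeptidePopulation.from_sequences(["HWPLPPF"], condition="other")
        with pytest.raises(ValueError):
            cross_condition_compare(build_catalog(pop, 5, 1))

    def test_sorted_by_distance_then_lexicographic(self):
        pairs = cross_condition_compare(self.make_catalog(), top_k=50,
                                        max_distance=0.8)
        keys = [(p.distance, p.condition_a, p.motif_a, p.condition_b, p.motif_b)
                for p in pairs]
        assert keys == sorted(keys)


class TestSharedCores:
    def test_disjoint_populations_share_nothing(self):
        a = PeptidePopulation.from_sequences(["AAAAAAA"])
        b = PeptidePopulation.from_sequences(["CCCCCCC"])
        assert shared_cores(a, b, 5) == set()

    def test_embedded_core_found(self):
        a = PeptidePopulation.from_sequences(["GGHWPLPPFKK", "AAAAAAA"])
        b = PeptidePopulation.from_sequences(["VHWPLPPFLI"])
        assert "HWPLPPF" in shared_cores(a, b, 7)

    def test_symmetry(self, random_peptides):
        a = PeptidePopulation.from_sequences(random_peptides[:50])
        b = PeptidePopulation.from_sequences(random_peptides[50:100])
        assert shared_cores(a, b, 5) == shared_cores(b, a, 5)
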