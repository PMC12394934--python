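import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cupep.core import Peptide, PeptidePopulation
from cupep.profiles import (BackgroundProfile, enrichment_ratio,
                            global_composition, positional_matrix,
                            positional_matrix_by_condition,
                            rice_bran_background)


def pop_of(seqs, condition="other"):
    return PeptidePopulation.from_sequences(seqs, condition=condition)


class TestGlobalComposition:
    def test_two_residue_toy(self):
        prof = global_composition(pop_of(["GG", "PP"]))
        assert prof.percent["G"] == pytest.approx(50.0)
        assert prof.percent["P"] == pytest.approx(50.0)
        assert prof.percent.drop(["G", "P"]).eq(0).all()

    def test_single_residue(self):
        prof = global_composition(pop_of(["H"]))
        assert prof.percent["H"] == pytest.approx(100.0)

    def test_duplication_invariance(self):
        seqs = ["HWPLPPF", "ASEGG"]
        a = global_composition(pop_of(seqs))
        b = global_composition(pop_of(seqs * 2))
        pd.testing.assert_series_equal(a.percent, b.percent)

    def test_percent_sums_to_100(self, random_peptides):
        prof = global_composition(pop_of(random_peptides[:200]))
        assert prof.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_composition(PeptidePopulation([], "empty"))


class TestEnrichmentRatio:
    def test_arithmetic(self):
        obs = global_composition(pop_of(["GG", "PP"]))  # G 50, P 50
        bg = BackgroundProfile(pd.Series(
            {aa: 0.0 for aa in obs.percent.index} | {"G": 25.0, "P": 10.0}))
        ratio = enrichment_ratio(obs, bg)
        assert ratio["G"] == pytest.approx(2.0)
        assert ratio["P"] == pytest.approx(5.0)

    def test_identity_when_observed_equals_background(self):
        obs = global_composition(pop_of(["HWPLPPF", "ASEGG"]))
        bg = BackgroundProfile(obs.percent.copy())
        ratio = enrichment_ratio(obs, bg).dropna()
        np.testing.assert_allclose(ratio.to_numpy(), 1.0)

    def test_his_enrichment_vs_typical_abundance(self):
        # 14% observed over a 2% background: sevenfold enrichment
        obs = global_composition(pop_of(["H" * 14 + "A" * 86]))
        bg = rice_bran_background()  # His 2.0 in the shipped example
        assert enrichment_ratio(obs, bg)["H"] == pytest.approx(7.0)

    def test_background_zero_gives_nan_not_inf(self):
        obs = global_composition(pop_of(["GG"]))
        bg = BackgroundProfile(pd.Series({aa: 0.0 for aa in obs.percent.index}))
        assert enrichment_ratio(obs, bg).isna().all()


class TestPositionalMatrix:
    def test_hand_countable(self):
        pm = positional_matrix(pop_of(["HAGLY", "GAGLY"]))
        assert pm.matrix.loc["H", "N1"] == pytest.approx(50.0)
        assert pm.matrix.loc["G", "N1"] == pytest.approx(50.0)
        assert pm.matrix.loc["A", "N2"] == pytest.approx(100.0)

    def test_length5_middle_residue_in_both_windows(self):
        pm = positional_matrix(pop_of(["ABCDE".replace("B", "C")]))  # ACCDE
        assert pm.matrix.loc["C", "N3"] == pytest.approx(100.0)
        assert pm.matrix.loc["C", "C3"] == pytest.approx(100.0)

    def test_columns_sum_to_100(self, random_peptides):
        pm = positional_matrix(pop_of(random_peptides[:300]))
        np.testing.assert_allclose(pm.matrix.sum(axis=0), 100.0, atol=1e-6)

    def test_short_peptides_excluded_and_counted(self):
        pm = positional_matrix(pop_of(["HAGLY", "GAG"]))
        assert pm.n_peptides == 1 and pm.n_excluded == 1

    def test_all_short_rejected(self):
        with pytest.raises(ValueError):
            positional_matrix(pop_of(["GAG", "AG"]))

    def test_order_invariance(self, random_peptides):
        seqs = random_peptides[:100]
        a = positional_matrix(pop_of(seqs)).matrix
        b = positional_matrix(pop_of(seqs[::-1])).matrix
        pd.testing.assert_frame_equal(a, b)


class TestByCondition:
    def test_single_condition_equals_pooled(self, random_peptides):
        pop = pop_of(random_peptides[:100], condition="papain")
        out = positional_matrix_by_condition(pop)
        pd.testing.assert_frame_equal(out["papain"].matrix, out["pooled"].matrix)

    def test_disjoint_single_peptide_conditions_are_indicators(self):
        pop = PeptidePopulation([
            Peptide("HAGLY", condition="pep_tryp"),
            Peptide("GAGLY", condition="papain"),
        ])
        out = positional_matrix_by_condition(pop)
        for cond in ("pep_tryp", "papain"):
            vals = out[cond].matrix.to_numpy()
            assert set(np.unique(vals)) == {0.0, 100.0}

    def test_unknown_condition_listed(self, two_condition_population):
        with pytest.raises(ValueError, match="papain"):
            positional_matrix_by_condition(two_condition_population,
                                           conditions=["other"])

    def test_pooled_is_count_weighted_average(self, random_peptides):
        pop = PeptidePopulation(
            [Peptide(s, condition="pep_tryp") for s in random_peptides[:150]]
            + [Peptide(s, condition="papain") for s in random_peptides[150:250]])
        out = positional_matrix_by_condition(pop)
        na, nb = out["pep_tryp"].n_peptides, out["papain"].n_peptides
        weighted = (out["pep_tryp"].matrix * na + out["papain"].matrix * nb) / (na + nb)
        pd.testing.assert_frame_equal(out["pooled"].matrix, weighted)

    def test_his_n1_rates_recovered_from_constructed_conditions(self, rng):
        """Two synthetic conditions built with His-at-N1 rates 0.5 and 0.1
        show per-condition N1-His frequencies inside the binomial CI."""
        n = 500
        peps = []
        for cond, rate in (("pep_tryp", 0.5), ("papain", 0.1)):
            for _ in range(n):
                first = "H" if rng.random() < rate else "A"
                body = "".join(rng.choice(list("ACDEFGIKLMNPQRSTVWY"), size=7))
                peps.append(Peptide(first + body, condition=cond))
        out = positional_matrix_by_condition(PeptidePopulation(peps))
        for cond, rate in (("pep_tryp", 0.5), ("papain", 0.1)):
            freq = out[cond].matrix.loc["H", "N1"] / 100.0
            half = 1.96 * np.sqrt(rate * (1 - rate) / n)
            assert abs(freq - rate) < half + 1e-9


class TestBackgroundFile:
    def test_shipped_example_sums_to_100(self):
        bg = rice_bran_background()
        assert bg.percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert bg.percent["G"] == 6.5 and bg.percent["P"] == 9.0
        assert bg.percent["H"] == 2.0
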