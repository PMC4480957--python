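"""Locus profiles, categories, overlap, sensitivity model, Fisher test."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from mechanista import (MechanismCall, ProteinRecord, delta_a_from_fold,
                        delta_p_from_or, enrichment_by_mechanism,
                        fisher_two_tailed, fold_from_delta_a,
                        linear_phenotype, locus_category,
                        locus_mechanism_profile, overlap_fraction,
                        selection_threshold, sensitivity_coefficient)


def _calls(*mechs):
    return [MechanismCall(locus_id="L", gene_id="G", snp_id=f"rs{i}",
                          mechanism=m) for i, m in enumerate(mechs)]


class TestLocusProfile:
    def test_missense_collapses_high_dominates(self):
        s = locus_mechanism_profile("L", "d", _calls(
            "missense_high", "missense_low", "expression"))
        assert s.mechanisms_present == frozenset({"missense_high",
                                                  "expression"})
        assert s.n_mechanism_types == 2

    def test_no_calls_gives_zero(self):
        s = locus_mechanism_profile("L", "d", [])
        assert s.n_mechanism_types == 0
        assert s.mechanisms_present == frozenset()

    def test_all_five_call_types_count_as_four(self):
        s = locus_mechanism_profile("L", "d", _calls(
            "missense_high", "missense_low", "expression", "aux_splice",
            "direct_splice"))
        assert s.n_mechanism_types == 4
        assert "missense_low" not in s.mechanisms_present

    def test_profile_order_invariant(self):
        calls = _calls("aux_splice", "missense_low", "expression")
        a = locus_mechanism_profile("L", "d", calls)
        b = locus_mechanism_profile("L", "d", calls[::-1])
        assert a.mechanisms_present == b.mechanisms_present
        assert a.n_mechanism_types == b.n_mechanism_types


def _prot(relevance, gene="G", known=True, mechanisms=()):
    return ProteinRecord(gene_id=gene, disease="d", relevance=relevance,
                         known=known, mechanisms=set(mechanisms),
                         is_mhc=relevance == "D")


class TestLocusCategory:
    @pytest.mark.parametrize("labels,expected", [
        (["A", "C"], "A"),
        (["B", "C"], "B"),
        (["C"], "C"),
        ([], "none"),
        (["D", "C"], "C"),
    ])
    def test_precedence(self, labels, expected):
        prots = [_prot(r, gene=f"G{i}") for i, r in enumerate(labels)]
        assert locus_category(prots) == expected

    def test_permutation_invariant(self):
        prots = [_prot(r, gene=f"G{i}") for i, r in
                 enumerate(["C", "B", "A", "C"])]
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = list(prots)
            rng.shuffle(perm)
            assert locus_category(perm) == "A"


class TestOverlapFraction:
    def test_worked_ratio(self):
        prots = ([_prot("B", gene=f"s{i}",
                        mechanisms={"aux_splice", "expression"})
                  for i in range(83)]
                 + [_prot("B", gene=f"t{i}", mechanisms={"aux_splice"})
                    for i in range(275 - 83)])
        assert overlap_fraction(prots, "aux_splice", "expression") == \
            pytest.approx(83 / 275)

    def test_disjoint_sets_give_zero(self):
        prots = [_prot("B", gene="a", mechanisms={"expression"}),
                 _prot("B", gene="b", mechanisms={"aux_splice"})]
        assert overlap_fraction(prots, "expression", "aux_splice") == 0

    def test_subset_gives_one(self):
        prots = [_prot("B", gene="a", mechanisms={"expression",
                                                  "missense_high"})]
        assert overlap_fraction(prots, "expression", "missense_high") == 1

    def test_empty_denominator_is_missing(self):
        assert overlap_fraction([], "expression", "aux_splice") is None


class TestSensitivityModel:
    def test_five_fold_loss(self):
        assert delta_a_from_fold(5, gain=False) == pytest.approx(-0.8)

    def test_fold_one_is_neutral(self):
        assert delta_a_from_fold(1) == 0

    def test_two_fold_loss(self):
        assert delta_a_from_fold(2) == pytest.approx(-0.5)

    def test_gain_direction(self):
        assert delta_a_from_fold(3, gain=True) == pytest.approx(2.0)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            delta_a_from_fold(0.5)

    def test_fold_round_trip_identity(self):
        for fold in np.linspace(1, 100, 50):
            assert fold_from_delta_a(delta_a_from_fold(fold)) == \
                pytest.approx(fold)
            assert fold_from_delta_a(delta_a_from_fold(fold, gain=True)) == \
                pytest.approx(fold)

    @pytest.mark.parametrize("odds,expected", [(1.84, 0.84), (1.0, 0.0),
                                               (2.5, 1.5)])
    def test_delta_p(self, odds, expected):
        assert delta_p_from_or(odds) == pytest.approx(expected)

    def test_sensitivity_magnitude_and_signed(self):
        assert sensitivity_coefficient(0.84, -0.8) == pytest.approx(1.05)
        assert sensitivity_coefficient(0.0, 0.3) == 0
        assert sensitivity_coefficient(0.84, -0.8, use_magnitude=False) == \
            pytest.approx(-1.05)
        with pytest.raises(ValueError):
            sensitivity_coefficient(0.5, 0.0)

    def test_linear_phenotype(self):
        assert linear_phenotype([1, 2], [0.1, -0.05]) == pytest.approx(0)
        assert linear_phenotype([1.05], [-0.8]) == pytest.approx(-0.84)
        assert linear_phenotype([], []) == 0
        with pytest.raises(ValueError):
            linear_phenotype([1], [])

    @pytest.mark.parametrize("ne,expected", [(10_000, 5e-5), (1, 0.5),
                                             (500, 1e-3)])
    def test_selection_threshold(self, ne, expected):
        assert selection_threshold(ne) == pytest.approx(expected)

    def test_selection_threshold_rejects_tiny_ne(self):
        with pytest.raises(ValueError):
            selection_threshold(0.5)


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed(5, 5, 5, 5) == 1

    def test_enumerated_small_table(self):
        assert fisher_two_tailed(3, 1, 1, 3) == Fraction(34, 70)

    def test_extreme_table(self):
        from math import comb
        assert fisher_two_tailed(10, 0, 0, 10) == Fraction(2, comb(20, 10))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(0, 0, 3, 4)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(1.5, 2, 3, 4)

    def test_agreement_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, 4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            ours = float(fisher_two_tailed(a, b, c, d))
            _, theirs = stats.fisher_exact([[a, b], [c, d]],
                                           alternative="two-sided")
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


class TestEnrichment:
    def _proteins(self, n_known_with, n_known_without, n_unknown_with,
                  n_unknown_without):
        prots = []
        for i in range(n_known_with):
            prots.append(_prot("B", gene=f"kw{i}", known=True,
                               mechanisms={"expression"}))
        for i in range(n_known_without):
            prots.append(_prot("B", gene=f"ko{i}", known=True))
        for i in range(n_unknown_with):
            prots.append(_prot("C", gene=f"uw{i}", known=False,
                               mechanisms={"expression"}))
        for i in range(n_unknown_without):
            prots.append(_prot("C", gene=f"uo{i}", known=False))
        return prots

    def test_single_gene_gives_p_one(self):
        df = enrichment_by_mechanism(self._proteins(1, 0, 0, 0))
        assert (df.p_value == 1.0).all()

    def test_no_eligible_genes_rejected(self):
        with pytest.raises(ValueError):
            enrichment_by_mechanism([])

    def test_mhc_proteins_excluded(self):
        prots = self._proteins(5, 5, 5, 5) + [_prot("D", gene="mhc1")]
        df = enrichment_by_mechanism(prots)
        row = df[df.mechanism == "expression"].iloc[0]
        assert row[["known_with", "unknown_with", "known_without",
                    "unknown_without"]].sum() == 20

    def test_p_decreases_with_planted_effect_strength(self):
        # mechanism progressively concentrated in known proteins
        ps = []
        for k in (10, 15, 20):
            prots = self._proteins(k, 20 - k, 20 - k, k)
            df = enrichment_by_mechanism(prots)
            ps.append(float(df[df.mechanism == "expression"].p_value.iloc[0]))
        assert ps[0] > ps[1] > ps[2]

    def test_null_simulation_p_not_systematically_small(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(100):
            prots = []
            for i in range(40):
                prots.append(_prot("B" if i < 20 else "C", gene=f"g{i}",
                                   known=i < 20,
                                   mechanisms={"expression"}
                                   if rng.random() < 0.5 else set()))
            df = enrichment_by_mechanism(prots)
            pvals.append(float(df[df.mechanism == "expression"]
                               .p_value.iloc[0]))
        # discrete exact p-values under the null are stochastically >= U(0,1)
        assert np.mean(pvals) > 0.4
        assert np.mean(np.array(pvals) < 0.05) < 0.12
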