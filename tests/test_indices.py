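import math

import numpy as np
import pytest

from conftest import make_gene
from oracles import nc_oracle
from plastcub.genetics import genetic_code
from plastcub.indices import (
    cai,
    classify_codons,
    count_codons,
    expected_nc,
    index_table,
    mrcbs,
    nc_wright,
    rcb_table,
    rscu,
)
from plastcub.synthetic import sample_cds


class TestCountCodons:
    def test_stop_codons_go_to_a_separate_ledger(self):
        table = count_codons(make_gene(["ATG", "AAA", "TAA"]))
        assert table.counts["ATG"] == 1
        assert table.counts["AAA"] == 1
        assert table.stop_counts == {"TAA": 1}
        assert table.total == 2

    def test_pooled_counts_are_additive(self, small_gene_set):
        pooled = count_codons(small_gene_set)
        per_gene = [count_codons(g) for g in small_gene_set]
        for codon in pooled.counts:
            assert pooled.counts[codon] == sum(t.counts[codon] for t in per_gene)

    def test_positional_counts_cover_every_sense_codon(self, small_gene_set):
        table = count_codons(small_gene_set)
        for k in range(3):
            assert sum(table.positional[k].values()) == table.total


class TestRscu:
    def test_two_codon_family_direct_formula(self):
        table = count_codons(make_gene(["AAA"] * 3 + ["AAG"]))
        values = rscu(table)
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_uniform_six_fold_family_is_unbiased(self):
        gc = genetic_code(11)
        table = count_codons(make_gene(list(gc.families["L"]) * 2))
        values = rscu(table)
        for codon in gc.families["L"]:
            assert values[codon] == pytest.approx(1.0)

    def test_unused_family_yields_nan_not_zero(self):
        table = count_codons(make_gene(["AAA", "AAA"]))
        assert math.isnan(rscu(table)["GGG"])

    def test_family_sums_equal_degeneracy(self, small_gene_set):
        gc = genetic_code(11)
        values = rscu(count_codons(small_gene_set))
        for aa, codons in gc.families.items():
            total = sum(values[c] for c in codons)
            assert total == pytest.approx(len(codons), abs=1e-9)


class TestRcb:
    def test_single_codon_table_has_zero_bias(self):
        table = count_codons(make_gene(["ATG", "ATG"]))
        assert rcb_table(table)["ATG"] == pytest.approx(0.0)

    def test_independence_null_gives_zero_for_all_codons(self):
        # all four Gly codons equally: position 1/2 fixed, position 3 uniform,
        # so each observed frequency equals the positional product exactly
        table = count_codons(make_gene(list(genetic_code(11).families["G"]) * 5))
        values = rcb_table(table)
        for codon in genetic_code(11).families["G"]:
            assert values[codon] == pytest.approx(0.0, abs=1e-12)

    def test_overused_codon_is_positive_underused_negative(self):
        # AAA/GAG co-occur more than positional independence allows
        codons = ["AAA"] * 5 + ["AAG"] + ["GAA"] + ["GAG"] * 3
        values = rcb_table(count_codons(make_gene(codons)))
        assert values["AAA"] == pytest.approx(0.5 / 0.36 - 1)
        assert values["AAG"] == pytest.approx(0.1 / 0.24 - 1)
        assert values["AAA"] > 0
        assert values["AAG"] < 0


class TestCai:
    def test_gene_of_family_maximal_codons_scores_one(self, small_gene_set):
        ref = index_table(count_codons(small_gene_set))
        gc = genetic_code(11)
        best = [max(fam, key=lambda c: ref.rscu[c])
                for fam in gc.families.values() if len(fam) >= 2]
        assert cai(make_gene(best), ref) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # Lys usage 4:1 -> w(AAG) = 0.25; gene with one AAA and one AAG
        ref = index_table(count_codons(make_gene(["AAA"] * 4 + ["AAG"])))
        assert ref.w["AAG"] == pytest.approx(0.25)
        value = cai(make_gene(["AAA", "AAG"]), ref)
        assert value == pytest.approx(math.sqrt(0.25 * 1.0))

    def test_invariant_under_codon_order_permutation(self, small_gene_set):
        ref = index_table(count_codons(small_gene_set))
        gene = small_gene_set[0]
        rng = np.random.default_rng(0)
        shuffled = make_gene(rng.permutation(list(gene.codons)))
        assert cai(gene, ref) == pytest.approx(cai(shuffled, ref))

    def test_gene_with_no_eligible_codons_raises(self, small_gene_set):
        ref = index_table(count_codons(small_gene_set))
        with pytest.raises(ValueError):
            cai(make_gene(["ATG", "TGG", "TAA"]), ref)


class TestMrcbs:
    def test_family_maximal_rcbs_codons_score_one(self, small_gene_set):
        ref = index_table(count_codons(small_gene_set))
        gc = genetic_code(11)
        best = [max(fam, key=ref.rcbs)
                for fam in gc.families.values() if len(fam) >= 2]
        assert mrcbs(make_gene(best), ref) == pytest.approx(1.0)

    def test_scale_free_under_count_multiplication(self, small_gene_set):
        ref1 = index_table(count_codons(small_gene_set))
        ref10 = index_table(count_codons(small_gene_set * 10))
        gene = small_gene_set[3]
        assert mrcbs(gene, ref1) == pytest.approx(mrcbs(gene, ref10))

    def test_invariant_under_codon_order_permutation(self, small_gene_set):
        ref = index_table(count_codons(small_gene_set))
        gene = small_gene_set[1]
        rng = np.random.default_rng(1)
        shuffled = make_gene(rng.permutation(list(gene.codons)))
        assert mrcbs(gene, ref) == pytest.approx(mrcbs(shuffled, ref))


class TestNcWright:
    def test_one_codon_per_family_reaches_the_minimum_20(self):
        gc = genetic_code(11)
        codons = []
        for fam in gc.families.values():
            codons.extend([fam[0]] * 2)      # m >= 2, single codon used
        assert nc_wright(make_gene(codons)) == 20.0

    def test_uniform_synonymous_usage_saturates_at_61(self):
        gc = genetic_code(11)
        codons = list(gc.sense_codons) * 100
        assert nc_wright(make_gene(codons)) == pytest.approx(61.0)

    def test_missing_class_makes_nc_undefined(self):
        assert math.isnan(nc_wright(make_gene(["AAA", "AAG"])))

    def test_agrees_with_family_enumeration_oracle(self):
        genes, _ = sample_cds(200, mean_len=100, theta=0.3, seed=5)
        checked = 0
        for gene in genes:
            ours = nc_wright(gene)
            theirs = nc_oracle(gene.codons)
            if math.isnan(theirs):
                assert math.isnan(ours)
                continue
            assert ours == pytest.approx(theirs, abs=0.5)
            checked += 1
        assert checked >= 150


class TestExpectedNc:
    @pytest.mark.parametrize(
        "s,value",
        [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0),
         (0.2596, 2 + 0.2596 + 29 / (0.2596**2 + 0.7404**2))],
    )
    def test_direct_evaluation(self, s, value):
        assert expected_nc(s) == pytest.approx(value)

    def test_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            expected_nc(1.2)


class TestClassification:
    @pytest.mark.parametrize(
        "r,b,expected",
        [
            (1.5, 0.2, {"preferred", "over_represented", "optimal"}),
            (0.4, -0.3, {"rare"}),
            (1.799, 0.139, {"preferred", "over_represented", "optimal"}),
            (0.9, -0.1, set()),
        ],
    )
    def test_rule_application(self, r, b, expected):
        flags = classify_codons({"GCT": r}, {"GCT": b})["GCT"]
        assert flags == frozenset(expected)


class TestMonotonicity:
    def test_theta_increases_bias_decreases_nc(self):
        means = []
        for i, theta in enumerate([0.0, 0.5, 1.0]):
            genes, _ = sample_cds(20, mean_len=300, theta=theta, seed=30 + i)
            values = [nc_wright(g) for g in genes]
            means.append(np.nanmean(values))
        assert means[0] > means[1] > means[2]
        assert means[2] == pytest.approx(20.0)
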