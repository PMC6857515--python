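import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from ilskit.coalescent import SpeciesTreeModel
from ilskit.retro import (
    ABSENT,
    AUTAPOMORPHY,
    INFORMATIVE,
    MISSING_LINEAGE,
    OMITTED,
    PRESENT,
    SYMPLESIOMORPHY,
    UNINFORMATIVE,
    InsertionMatrix,
    classify_patterns,
    generate_insertion_dataset,
    kksc_tree_test,
    minor_symmetry_test,
    species_tree_consistency_report,
    tally_trio_support,
)
from ilskit.treecore import parse_newick


def matrix_from_rows(rows, taxa):
    data = pd.DataFrame(rows, columns=taxa, index=[f"L{i}" for i in range(len(rows))])
    return InsertionMatrix(data)


SIX = ["A", "B", "C", "D", "E", "F"]
SIX_LINEAGES = {"A": "l1", "B": "l1", "C": "l2", "D": "l2", "E": "l3", "F": "l3"}


class TestInsertionMatrix:
    def test_tsv_round_trip(self, tmp_path):
        m = matrix_from_rows([[1, 1, 0, 0, -1, 0]], SIX)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = InsertionMatrix.from_tsv(path)
        assert back.data.equals(m.data)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            matrix_from_rows([[1, 2, 0, 0, 0, 0]], SIX)

    def test_fully_omitted_locus_rejected(self):
        with pytest.raises(ValueError):
            matrix_from_rows([[-1] * 6], SIX)


class TestClassifyPatterns:
    def test_pair_presence_is_informative(self):
        m = matrix_from_rows([[1, 1, 0, 0, 0, 0]], SIX)
        (pc,) = classify_patterns(m, SIX_LINEAGES)
        assert pc.label == INFORMATIVE
        assert pc.presence == frozenset("AB")

    def test_presence_in_all_scored_is_symplesiomorphy(self):
        m = matrix_from_rows([[1, 1, 1, 1, 1, 1], [1, 1, 1, -1, 1, 1]], SIX)
        labels = [pc.label for pc in classify_patterns(m, SIX_LINEAGES)]
        assert labels == [SYMPLESIOMORPHY, SYMPLESIOMORPHY]

    def test_single_presence_is_autapomorphy(self):
        m = matrix_from_rows([[0, 1, 0, 0, 0, 0]], SIX)
        assert classify_patterns(m, SIX_LINEAGES)[0].label == AUTAPOMORPHY

    def test_missing_lineage_omitted(self):
        m = matrix_from_rows([[1, 1, 0, 0, -1, -1]], SIX)
        assert classify_patterns(m, SIX_LINEAGES)[0].label == MISSING_LINEAGE

    def test_no_presence_is_uninformative(self):
        classes = classify_patterns(
            matrix_from_rows([[0, 0, 0, 0, 0, 0]], SIX), SIX_LINEAGES
        )
        assert classes[0].label == UNINFORMATIVE

    def test_unmapped_taxon_raises(self):
        m = matrix_from_rows([[1, 1, 0, 0, 0, 0]], SIX)
        with pytest.raises(ValueError):
            classify_patterns(m, {"A": "l1"})

    def test_labels_partition_generated_loci(self, small_scenario):
        matrix, truth = generate_insertion_dataset(
            small_scenario.model, 400, seed=3, omission_rate=0.0
        )
        classes = classify_patterns(matrix, small_scenario.spec.lineage_map)
        assert len(classes) == 400
        observed = Counter(pc.label for pc in classes)
        expected = Counter(truth["true_class"])
        # without omission noise, classification equals generator bookkeeping
        assert observed == expected


class TestTallyTrioSupport:
    def test_engineered_12_1_1(self):
        rows = (
            [[1, 1, 1, 1, 0, 0]] * 12  # unites l1 + l2, excludes l3
            + [[1, 1, 0, 0, 1, 0]]  # unites l1 + l3
            + [[0, 0, 1, 0, 1, 1]]  # unites l2 + l3
        )
        m = matrix_from_rows(rows, SIX)
        classes = classify_patterns(m, SIX_LINEAGES)
        tally = tally_trio_support(classes, SIX_LINEAGES, ("l1", "l2", "l3"))
        assert tally.as_counts() == (12, 1, 1)
        assert kksc_tree_test(*tally.as_counts()).p == pytest.approx(8.2e-5, abs=5e-6)

    def test_no_informative_loci(self):
        m = matrix_from_rows([[1, 1, 1, 1, 1, 1]], SIX)
        classes = classify_patterns(m, SIX_LINEAGES)
        tally = tally_trio_support(classes, SIX_LINEAGES, ("l1", "l2", "l3"))
        assert tally.as_counts() == (0, 0, 0)

    def test_lineage_without_members_raises(self):
        with pytest.raises(ValueError):
            tally_trio_support([], SIX_LINEAGES, ("l1", "l2", "nope"))

    def test_hemiplasy_minor_counts_symmetric(self):
        t = 0.15
        sp = parse_newick(f"((A:0.5,B:0.5):{t},C:0.7);")
        model = SpeciesTreeModel(sp)
        matrix, _ = generate_insertion_dataset(model, 6000, seed=8, stem_length=0.3)
        lmap = {"A": "la", "B": "lb", "C": "lc"}
        classes = classify_patterns(matrix, lmap)
        tally = tally_trio_support(classes, lmap, ("la", "lb", "lc"))
        _, n2, n3 = tally.as_counts()
        assert binomtest(n2, n2 + n3, 0.5).pvalue > 0.01

    def test_trio_fraction_matches_length_weighted_expectation(self):
        # under length-proportional insertion placement the expected pattern
        # weights are (t + e^-t/3) : e^-t/3 : e^-t/3
        t = 0.1
        sp = parse_newick(f"((A:0.5,B:0.5):{t},C:0.7);")
        matrix, _ = generate_insertion_dataset(
            SpeciesTreeModel(sp), 8000, seed=17, stem_length=0.3
        )
        lmap = {"A": "la", "B": "lb", "C": "lc"}
        classes = classify_patterns(matrix, lmap)
        n1, n2, n3 = tally_trio_support(classes, lmap, ("la", "lb", "lc")).as_counts()
        total = n1 + n2 + n3
        expected = (t + math.exp(-t) / 3) / (t + math.exp(-t))
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(n1 / total - expected) < 3 * se


class TestKKSCTreeTest:
    def test_reference_counts_12_1_1(self):
        assert float(f"{kksc_tree_test(12, 1, 1).p:.2g}") == 8.2e-05

    def test_reference_counts_12_6_5(self):
        assert float(f"{kksc_tree_test(12, 6, 5).p:.2g}") == 0.048

    def test_empty_data(self):
        assert kksc_tree_test(0, 0, 0).p == 1.0

    def test_balanced_counts(self):
        assert kksc_tree_test(5, 5, 5).p == pytest.approx(0.5959352165, rel=1e-9)

    @pytest.mark.parametrize("n1", [1, 3, 7])
    def test_clean_support_closed_form(self, n1):
        assert kksc_tree_test(n1, 0, 0).p == pytest.approx((1 / 3) ** n1, rel=1e-12)

    def test_monotone_decreasing_in_n1(self):
        ps = [kksc_tree_test(n1, 6, 5).p for n1 in range(1, 15)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_matches_trinomial_enumeration(self):
        # independent oracle: enumerate all trinomial outcomes
        def oracle(n1, n2, n3):
            n = n1 + n2 + n3
            p = 0.0
            for a in range(n + 1):
                for b in range(n - a + 1):
                    c = n - a - b
                    if a >= n1:
                        p += (
                            math.comb(n, a)
                            * math.comb(n - a, b)
                            * (1 / 3) ** n
                        )
            return p

        for n1, n2, n3 in [(0, 0, 1), (2, 1, 0), (4, 4, 4), (6, 3, 2), (12, 0, 0)]:
            assert kksc_tree_test(n1, n2, n3).p == pytest.approx(
                oracle(n1, n2, n3), rel=1e-10
            )

    def test_log_space_agrees_with_direct_sum(self):
        for total in range(1, 31):
            n1 = total // 2
            direct = sum(
                math.comb(total, k) * (1 / 3) ** k * (2 / 3) ** (total - k)
                for k in range(n1, total + 1)
            )
            assert kksc_tree_test(n1, total - n1, 0).p == pytest.approx(
                direct, rel=1e-10
            )

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            kksc_tree_test(-1, 2, 3)

    def test_p_in_unit_interval(self):
        for n1, n2, n3 in itertools.product(range(5), repeat=3):
            if n1 + n2 + n3 == 0:
                continue
            p = kksc_tree_test(n1, n2, n3).p
            assert 0 < p <= 1


class TestMinorSymmetryTest:
    def test_near_symmetric_counts(self):
        assert minor_symmetry_test(6, 5) == pytest.approx(1.0)

    def test_fully_asymmetric_counts(self):
        assert minor_symmetry_test(10, 0) == pytest.approx(0.001953125, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_perfect_symmetry(self, k):
        assert minor_symmetry_test(k, k) == pytest.approx(1.0)

    def test_no_minors_raises(self):
        with pytest.raises(ValueError):
            minor_symmetry_test(0, 0)


class TestConsistencyReport:
    SP = "(((A,B),(C,D)),(E,F));"

    def test_all_presence_clusters_on_tree(self):
        rows = [[1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0], [0, 0, 0, 0, 1, 1]]
        m = matrix_from_rows(rows, SIX)
        classes = classify_patterns(m, SIX_LINEAGES)
        report = species_tree_consistency_report(classes, parse_newick(self.SP))
        assert report.fraction_consistent == 1.0
        assert report.per_edge[frozenset("AB")] == 1

    def test_engineered_conflicts(self):
        consistent = [[1, 1, 0, 0, 0, 0]] * 8
        conflicting = [[1, 0, 1, 0, 0, 0]] * 2
        m = matrix_from_rows(consistent + conflicting, SIX)
        classes = classify_patterns(m, SIX_LINEAGES)
        report = species_tree_consistency_report(classes, parse_newick(self.SP))
        assert (report.n_consistent, report.n_informative) == (8, 10)
        assert len(report.conflicting_loci) == 2

    def test_restriction_to_scored_taxa(self):
        # presence {A, C} looks conflicting, but with B and D omitted the
        # restricted species tree has an {A, C} cluster
        m = matrix_from_rows([[1, -1, 1, -1, 0, 0]], SIX)
        classes = classify_patterns(m, SIX_LINEAGES)
        report = species_tree_consistency_report(classes, parse_newick(self.SP))
        assert report.n_consistent == 1

    def test_long_branch_simulation_rarely_conflicts(self, small_scenario):
        from ilskit.synthetic import make_scenario

        scenario = make_scenario({"all_internal_tau": 5.0}, seed=21)
        matrix, _ = generate_insertion_dataset(
            scenario.model, 2000, seed=21, omission_rate=0.0
        )
        classes = classify_patterns(matrix, scenario.spec.lineage_map)
        report = species_tree_consistency_report(classes, scenario.model.tree)
        assert report.fraction_consistent > 0.99


class TestGenerateInsertionDataset:
    def test_stem_dominated_model_yields_symplesiomorphies(self):
        sp = parse_newick("((A:0.001,B:0.001):0.001,C:0.002);")
        matrix, truth = generate_insertion_dataset(
            SpeciesTreeModel(sp, default_theta=0.001, terminal_theta=0.001,
                             root_theta=0.001),
            100, seed=1, stem_length=1000.0,
        )
        assert set(truth["true_class"]) == {SYMPLESIOMORPHY}
        assert (matrix.data.to_numpy() == PRESENT).all()

    def test_terminal_dominated_model_yields_autapomorphies(self):
        sp = parse_newick("((A:50,B:50):0.001,C:50.001);")
        model = SpeciesTreeModel(sp, default_theta=1.0)
        _, truth = generate_insertion_dataset(model, 200, seed=2, stem_length=0.001)
        frac = (truth["true_class"] == AUTAPOMORPHY).mean()
        assert frac > 0.9

    def test_deterministic_given_seed(self, small_scenario):
        a, _ = generate_insertion_dataset(small_scenario.model, 50, seed=4,
                                          omission_rate=0.02)
        b, _ = generate_insertion_dataset(small_scenario.model, 50, seed=4,
                                          omission_rate=0.02)
        c, _ = generate_insertion_dataset(small_scenario.model, 50, seed=5,
                                          omission_rate=0.02)
        assert a.data.equals(b.data)
        assert not a.data.equals(c.data)

    def test_omission_rate_realized(self, small_scenario):
        matrix, _ = generate_insertion_dataset(
            small_scenario.model, 500, seed=6, omission_rate=0.05
        )
        frac = (matrix.data.to_numpy() == OMITTED).mean()
        n = matrix.data.size
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 4 * se
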