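import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binomtest

from ilskit.coalescent import (
    ModelError,
    SpeciesTreeModel,
    a_of_x,
    anomaly_fractions,
    anomaly_scan,
    branch_length_from_major_freq,
    expected_triplet_probs,
    fisher_exact_2xk,
    heterogeneity_ratio,
    read_mut_lengths,
    simulate_gene_trees,
    theta_from_lengths,
    triplet_gof,
    write_mut_lengths,
)
from ilskit.heterogeneity import decompose_triplets
from ilskit.treecore import GeneTreeSet, apply_random_nni, parse_newick


class TestThetaFromLengths:
    def test_simple_ratio(self):
        assert theta_from_lengths(0.005, 2.5) == pytest.approx(0.002)

    def test_zero_mut_length(self):
        assert theta_from_lengths(0.0, 1.0) == 0.0

    def test_round_trip_with_model(self):
        # muT = Theta * tau re-derives the Theta used to build the model
        sp = parse_newick("((A:1,B:1):0.5,C:2);")
        model = SpeciesTreeModel(sp, mut_lengths={frozenset("AB"): 0.01})
        assert model.theta[frozenset("AB")] == pytest.approx(
            theta_from_lengths(0.01, 0.5)
        )

    def test_nonpositive_tau_raises(self):
        with pytest.raises(ValueError):
            theta_from_lengths(0.01, 0.0)


class TestTripletExpectation:
    def test_polytomy_limit(self):
        e = expected_triplet_probs(0.0)
        assert e.as_probs() == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_no_ils_limit(self):
        e = expected_triplet_probs(50.0)
        assert e.major == pytest.approx(1.0)
        assert e.minor == pytest.approx(0.0, abs=1e-12)

    def test_reference_values_at_t_0p1(self):
        e = expected_triplet_probs(0.1)
        assert e.major == pytest.approx(0.39678, abs=5e-6)
        assert e.minor == pytest.approx(0.30161, abs=5e-6)

    def test_probabilities_sum_to_one_and_major_dominates(self):
        for t in np.linspace(0.0, 6.0, 25):
            e = expected_triplet_probs(t)
            assert e.major + 2 * e.minor == pytest.approx(1.0)
            assert e.major >= 1 / 3

    def test_monotone_in_t(self):
        majors = [expected_triplet_probs(t).major for t in np.linspace(0, 5, 40)]
        assert all(b > a for a, b in zip(majors, majors[1:]))

    def test_negative_t_raises(self):
        with pytest.raises(ValueError):
            expected_triplet_probs(-0.1)


class TestBranchLengthInversion:
    def test_inverse_of_reference_value(self):
        assert branch_length_from_major_freq(0.39678) == pytest.approx(0.1, abs=1e-4)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 3.0])
    def test_round_trip_exact(self, t):
        p = expected_triplet_probs(t).major
        assert branch_length_from_major_freq(p) == pytest.approx(t)

    def test_continuity_near_lower_bound(self):
        assert branch_length_from_major_freq(1 / 3 + 1e-9) < 1e-6

    @pytest.mark.parametrize("p", [0.2, 1 / 3, 1.0, 1.2])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            branch_length_from_major_freq(p)


class TestAnomalyBoundary:
    def test_closed_form_at_0p1(self):
        assert a_of_x(0.1) == pytest.approx(0.3266, abs=5e-4)

    def test_negative_for_long_branches(self):
        assert a_of_x(10.0) < 0
        assert a_of_x(10.0) == pytest.approx(math.log(2 / 3), abs=1e-3)

    def test_monotone_decreasing(self):
        xs = np.linspace(0.01, 5.0, 60)
        vals = [a_of_x(x) for x in xs]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_single_zero_crossing_near_0p2655(self):
        root = brentq(a_of_x, 0.1, 1.0)
        assert root == pytest.approx(0.2655, abs=5e-4)

    @pytest.mark.parametrize("x", [0.0, -1.0])
    def test_singular_at_zero(self, x):
        with pytest.raises(ValueError):
            a_of_x(x)


class TestAnomalyScan:
    def test_long_branches_flag_nothing(self):
        sp = parse_newick("((((A:1,B:1):5,C:1):5,D:1):5,E:2);")
        pairs = anomaly_scan(SpeciesTreeModel(sp))
        assert pairs and not any(p.anomalous for p in pairs)

    def test_short_successive_pair_flagged(self):
        sp = parse_newick("((((A:1,B:1):0.01,C:1):0.05,D:1):5,E:2);")
        pairs = anomaly_scan(SpeciesTreeModel(sp))
        flagged = [p for p in pairs if p.anomalous]
        assert len(flagged) == 1
        assert flagged[0].x == 0.05 and flagged[0].y == 0.01
        assert flagged[0].a_x == pytest.approx(a_of_x(0.05))

    def test_missing_tau_names_edge(self):
        sp = parse_newick("((((A:1,B:1),C:1):0.05,D:1):5,E:2);")
        with pytest.raises(ModelError, match="A,B"):
            anomaly_scan(SpeciesTreeModel(sp))

    def test_bootstrap_fractions(self):
        short = parse_newick("((((A:1,B:1):0.01,C:1):0.05,D:1):5,E:2);")
        long = parse_newick("((((A:1,B:1):3,C:1):0.05,D:1):5,E:2);")
        df = anomaly_fractions([SpeciesTreeModel(short), SpeciesTreeModel(long)])
        row = df[df["child"] == "A,B"].iloc[0]
        assert row["n_replicates"] == 2
        assert row["fraction_anomalous"] == 0.5


class TestSimulateGeneTrees:
    def test_same_seed_is_deterministic(self):
        sp = parse_newick("((A:1,B:1):0.5,C:2);")
        model = SpeciesTreeModel(sp)
        a = simulate_gene_trees(model, 20, seed=3)
        b = simulate_gene_trees(model, 20, seed=3)
        c = simulate_gene_trees(model, 20, seed=4)
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]
        assert [t.to_newick() for t in a] != [t.to_newick() for t in c]

    def test_long_branches_recover_species_topology(self):
        sp = parse_newick("((((A:1,B:1):50,C:1):50,D:1):50,E:2);")
        gts = simulate_gene_trees(SpeciesTreeModel(sp), 200, seed=5)
        assert all(t.clusters() == sp.clusters() for t in gts)

    @pytest.mark.parametrize("t", [0.05, 0.5])
    def test_trio_concordance_matches_analytic_oracle(self, t):
        n = 10_000
        sp = parse_newick(f"((A:1,B:1):{t},C:2);")
        gts = simulate_gene_trees(SpeciesTreeModel(sp), n, seed=21)
        conc = sum(
            1 for g in gts if decompose_triplets(g, ("A", "B", "C")) == frozenset("AB")
        )
        p = expected_triplet_probs(t).major
        se = math.sqrt(p * (1 - p) / n)
        assert abs(conc / n - p) < 3 * se

    def test_minor_topologies_exchangeable(self):
        # relabeling the two minor outcomes is distribution-identical
        sp = parse_newick("((A:1,B:1):0.3,C:2);")
        gts = simulate_gene_trees(SpeciesTreeModel(sp), 8000, seed=13)
        n2 = sum(
            1 for g in gts if decompose_triplets(g, ("A", "B", "C")) == frozenset("AC")
        )
        n3 = sum(
            1 for g in gts if decompose_triplets(g, ("A", "B", "C")) == frozenset("BC")
        )
        assert binomtest(n2, n2 + n3, 0.5).pvalue > 0.001

    def test_branch_lengths_scale_with_theta(self):
        # mutational height of the cherry node ~ theta on terminal branches
        sp = parse_newick("((A:5,B:5):5,C:10);")
        big = SpeciesTreeModel(sp, default_theta=2.0, terminal_theta=2.0, root_theta=2.0)
        small = SpeciesTreeModel(sp, default_theta=0.5, terminal_theta=0.5, root_theta=0.5)
        h_big = np.mean(
            [t.find_leaf("A").length for t in simulate_gene_trees(big, 200, seed=1)]
        )
        h_small = np.mean(
            [t.find_leaf("A").length for t in simulate_gene_trees(small, 200, seed=1)]
        )
        assert h_big == pytest.approx(4 * h_small, rel=0.05)


class TestHeterogeneityRatio:
    def test_degenerate_empirical_set_reports_undefined(self):
        sp = parse_newick("((A:1,B:1):1,C:2);")
        model = SpeciesTreeModel(sp)
        empirical = GeneTreeSet([sp.copy() for _ in range(10)])
        res = heterogeneity_ratio(empirical, model, n_sim=50, seed=0)
        assert not res.defined
        assert math.isnan(res.ratio)

    def test_metric_validation(self):
        sp = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            heterogeneity_ratio(
                GeneTreeSet([sp.copy()]), SpeciesTreeModel(sp), metric="nope"
            )


class TestFisherExact2xk:
    def test_matches_r_fisher_test(self):
        # frozen from R stats::fisher.test
        p, method = fisher_exact_2xk([[3, 1, 4], [2, 5, 0]])
        assert method == "exact"
        assert p == pytest.approx(0.049728049728, rel=1e-9)
        p2, _ = fisher_exact_2xk([[12, 6, 5], [8, 7, 8]])
        assert p2 == pytest.approx(0.493157081578, rel=1e-9)

    def test_monte_carlo_agrees_with_exact(self):
        table = [[12, 6, 5], [8, 7, 8]]
        p_exact, _ = fisher_exact_2xk(table)
        p_mc, method = fisher_exact_2xk(table, max_tables=1, n_mc=40_000, seed=2)
        assert method == "monte-carlo"
        se = math.sqrt(p_exact * (1 - p_exact) / 40_000)
        assert abs(p_mc - p_exact) < 4 * se

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk([[0, 0, 0], [0, 0, 0]])


class TestTripletGof:
    def test_observation_at_expectation_gives_one(self):
        t = branch_length_from_major_freq(0.5)
        assert triplet_gof((50, 25, 25), t) == pytest.approx(1.0)

    def test_concentrated_observation_vs_polytomy_null(self):
        # small analogue of an all-major observation against t = 0
        assert triplet_gof((10, 0, 0), 0.0) < 0.05

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            triplet_gof((0, 0, 0), 1.0)

    def test_calibration_on_simulated_counts(self):
        # counts simulated at the matching t should rarely reject
        t = 0.2
        probs = expected_triplet_probs(t).as_probs()
        rng = np.random.default_rng(99)
        rejections = 0
        n_seeds = 20
        for _ in range(n_seeds):
            counts = rng.multinomial(500, probs)
            if triplet_gof(tuple(counts), t) <= 0.05:
                rejections += 1
        assert rejections <= 1  # >= 95% of seeds fail to reject


class TestMutLengthSidecar:
    def test_round_trip(self, tmp_path):
        sp = parse_newick("((A:1,B:1):0.5,C:2);")
        model = SpeciesTreeModel(sp, mut_lengths={frozenset("AB"): 0.01, "A": 0.2})
        path = tmp_path / "mut.tsv"
        write_mut_lengths(model, path)
        back = read_mut_lengths(path)
        assert back[frozenset("AB")] == pytest.approx(0.01)
        assert back["A"] == pytest.approx(0.2)

    def test_inconsistent_triple_raises_with_identity(self):
        sp = parse_newick("((A:1,B:1):0.5,C:2);")
        with pytest.raises(ModelError, match="muT/tau"):
            SpeciesTreeModel(
                sp,
                mut_lengths={frozenset("AB"): 0.01},
                thetas={frozenset("AB"): 0.5},
            )
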