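import numpy as np
import pytest

import phylorecruit as pr
from phylorecruit.io_formats import MISSING
from phylorecruit.parsimony import _DP, _codes_for_tree

from .brute_oracle import brute_profile, random_topology


def _random_codes(rng, n_genes, n_leaves, p_missing=0.2):
    codes = rng.integers(0, 2, size=(n_genes, n_leaves)).astype(np.int8)
    codes[rng.random(codes.shape) < p_missing] = MISSING
    return codes


class TestScore:
    def test_one_change(self, three_taxon_tree):
        assert pr.parsimony_score(three_taxon_tree, {"A": 1, "B": 1, "C": 0}) == 1

    def test_constant_character_costs_nothing(self, five_taxon_tree):
        assert pr.parsimony_score(five_taxon_tree, dict.fromkeys("ABCDE", 1)) == 0

    def test_missing_leaf_is_free(self, three_taxon_tree):
        assert pr.parsimony_score(three_taxon_tree, {"A": 1, "B": "?", "C": 0}) == 1

    def test_leaf_without_state_is_hard_error(self, three_taxon_tree):
        with pytest.raises(KeyError, match="C"):
            pr.parsimony_score(three_taxon_tree, {"A": 1, "B": 0})

    def test_adding_missing_leaf_never_raises_score(self, rng):
        tree = pr.parse_newick("(((A,B),(C,D)),(E,F));")
        for _ in range(50):
            states = {leaf: int(rng.integers(0, 2)) for leaf in tree.leaf_labels}
            s0 = pr.parsimony_score(tree, states)
            leaf = tree.leaf_labels[rng.integers(6)]
            relaxed = {**states, leaf: "?"}
            assert pr.parsimony_score(tree, relaxed) <= s0

    def test_score_bounded_by_minority_state_count(self, rng):
        tree = pr.parse_newick("((((A,B),C),(D,E)),(F,(G,H)));")
        for _ in range(50):
            states = {leaf: int(rng.integers(0, 2)) for leaf in tree.leaf_labels}
            ones = sum(states.values())
            bound = min(ones, len(states) - ones)
            assert 0 <= pr.parsimony_score(tree, states) <= bound


class TestMPRProfile:
    def test_three_taxon_ambiguous_root(self, three_taxon_tree):
        prof = pr.mpr_profile(three_taxon_tree, {"A": 1, "B": 1, "C": 0})
        assert prof.score == 1
        assert prof.mpr_set["N1"] == {1}
        assert prof.mpr_set["R"] == {0, 1}

    def test_five_taxon_unique_reconstruction(self, five_taxon_tree):
        prof = pr.mpr_profile(five_taxon_tree,
                              {"A": 1, "B": 1, "C": 1, "D": 0, "E": 0})
        assert prof.score == 1
        assert prof.mpr_set["N1"] == {1} and prof.mpr_set["N2"] == {1}
        assert prof.mpr_set["N3"] == {0} and prof.mpr_set["R"] == {0}

    def test_constant_character_all_singletons(self, five_taxon_tree):
        prof = pr.mpr_profile(five_taxon_tree, dict.fromkeys("ABCDE", 1))
        assert prof.score == 0
        assert all(s == {1} for s in prof.mpr_set.values())

    def test_score_is_min_node_cost_everywhere(self, five_taxon_tree):
        prof = pr.mpr_profile(five_taxon_tree,
                              {"A": 1, "B": "?", "C": 0, "D": 1, "E": 0})
        for label in ("N1", "N2", "N3", "R"):
            assert min(prof.node_cost[label]) == prof.score

    def test_observed_leaf_mpr_is_its_state(self, three_taxon_tree):
        prof = pr.mpr_profile(three_taxon_tree, {"A": 1, "B": "?", "C": 0})
        assert prof.mpr_set["A"] == {1} and prof.mpr_set["C"] == {0}


class TestEdgeEvents:
    def test_unique_gain_edge(self, five_taxon_tree):
        events = {e.edge: e for e in pr.edge_events(
            five_taxon_tree, {"A": 1, "B": 1, "C": 1, "D": 0, "E": 0})}
        assert events[("N3", "N2")].category == "unambiguous_gain"
        others = [e for edge, e in events.items() if edge != ("N3", "N2")]
        assert all(e.category == "unambiguous_none" for e in others)

    def test_ambiguous_gain_and_loss(self, three_taxon_tree):
        events = {e.edge: e for e in pr.edge_events(
            three_taxon_tree, {"A": 1, "B": 1, "C": 0})}
        assert events[("R", "N1")].category == "possible_gain"
        assert events[("R", "C")].category == "possible_loss"

    def test_constant_character_no_events(self, five_taxon_tree):
        events = pr.edge_events(five_taxon_tree, dict.fromkeys("ABCDE", 1))
        assert all(e.category == "unambiguous_none" for e in events)

    def test_unambiguous_implies_possible(self, rng):
        tree = pr.parse_newick("(((A,B),(C,D)),(E,(F,G)));")
        for _ in range(30):
            states = {leaf: rng.choice([0, 1, "?"]) for leaf in tree.leaf_labels}
            for e in pr.edge_events(tree, states):
                if e.gain_unambiguous:
                    assert e.gain_possible
                if e.loss_unambiguous:
                    assert e.loss_possible
                assert len(e.pairs) >= 1

    def test_unambiguous_gain_iff_endpoint_mprs_are_0_and_1(self, rng):
        # joint-constraint call must match the node-marginal characterization
        tree = pr.parse_newick("((((A,B),C),(D,E)),(F,G));")
        for _ in range(50):
            states = {leaf: rng.choice([0, 1, "?"]) for leaf in tree.leaf_labels}
            prof = pr.mpr_profile(tree, states)
            for e in pr.edge_events(tree, states):
                u, v = e.edge
                marginal = prof.mpr_set[u] == {0} and prof.mpr_set[v] == {1}
                assert e.gain_unambiguous == marginal


class TestOracleAgreement:
    """The inside-outside DP must match exhaustive enumeration exactly."""

    def test_small_trees_random_characters(self, rng):
        for case in range(60):
            n_leaves = int(rng.integers(3, 9))
            tree = pr.parse_newick(random_topology(n_leaves, rng))
            codes = _random_codes(rng, 25, n_leaves)
            dp = _DP(tree, codes)
            ref = brute_profile(tree, codes)
            np.testing.assert_array_equal(dp.score.astype(int), ref["score"])
            for i in ref["internal"]:
                np.testing.assert_array_equal(dp.node_cost(i), ref["node_cost"][i])
            for i in range(len(tree.postorder)):
                np.testing.assert_array_equal(dp.mpr(i), ref["mpr"][i])
                if tree.parent[i] is not None:
                    np.testing.assert_array_equal(
                        dp.edge_pairs(i), ref["edge_pairs"][i]
                    )


class TestClassifyRecruitment:
    def test_three_character_matrix(self, five_taxon_tree):
        matrix = pr.CharacterMatrix.from_strings(
            ["g_gain", "g_const1", "g_const0"],
            list("ABCDE"),
            [list("11100"), list("11111"), list("00000")],
        )
        result = pr.classify_recruitment(five_taxon_tree, matrix, ["A", "C"])
        assert result.focal_edge == ("N3", "N2")
        assert result.classifications["g_gain"] == "unambiguous_gain"
        assert result.classifications["g_const1"] == "uninformative"
        assert result.classifications["g_const0"] == "uninformative"
        assert sum(result.counts.values()) == 3

    def test_focal_edge_at_root_is_error(self, five_taxon_tree):
        matrix = pr.CharacterMatrix.from_strings(
            ["g"], list("ABCDE"), [list("11100")])
        with pytest.raises(ValueError, match="root"):
            pr.classify_recruitment(five_taxon_tree, matrix, ["A", "E"])

    def test_single_gain_recovery_is_total(self, amniote):
        matrix = pr.simulate_single_gain_characters(
            amniote, "Eutheria", 200, missing_rate=0.0, seed=11)
        result = pr.classify_recruitment(amniote, matrix, pr.EUTHERIA)
        assert result.unambiguous_gains == 200
        assert result.most_parsimonious_gains == 200

    def test_classifications_mutually_exclusive_and_total(self, amniote, rng):
        config = pr.CharSimConfig(tree=amniote, n_genes=300, seed=5,
                                  gain_probability=0.1, loss_probability=0.1,
                                  missing_rate=0.15)
        matrix, _ = pr.simulate_characters(config)
        result = pr.classify_recruitment(amniote, matrix, pr.EUTHERIA)
        assert sum(result.counts.values()) == 300
        assert set(result.classifications.unique()) <= set(pr.parsimony.CLASSIFICATIONS)


class TestBranchChangeCounts:
    def test_counts_localize_single_gain(self, five_taxon_tree):
        matrix = pr.CharacterMatrix.from_strings(
            ["g_gain", "g_const1", "g_const0"],
            list("ABCDE"),
            [list("11100"), list("11111"), list("00000")],
        )
        counts = pr.branch_change_counts(five_taxon_tree, matrix)
        focal = counts[(counts.parent == "N3") & (counts.child == "N2")]
        assert focal.unambiguous_gains.item() == 1
        rest = counts[~((counts.parent == "N3") & (counts.child == "N2"))]
        assert (rest.unambiguous_gains == 0).all()
        assert (counts.unambiguous_losses == 0).all()

    def test_empty_matrix_all_zero(self, five_taxon_tree):
        matrix = pr.CharacterMatrix([], list("ABCDE"),
                                    np.empty((0, 5), dtype=np.int8))
        counts = pr.branch_change_counts(five_taxon_tree, matrix)
        for col in ("unambiguous_gains", "unambiguous_losses",
                    "possible_gains", "possible_losses"):
            assert (counts[col] == 0).all()

    def test_duplicating_rows_doubles_counts(self, amniote, rng):
        config = pr.CharSimConfig(tree=amniote, n_genes=80, seed=9,
                                  gain_probability=0.08, loss_probability=0.08)
        matrix, _ = pr.simulate_characters(config)
        doubled = pr.CharacterMatrix(
            matrix.genes + [g + "_dup" for g in matrix.genes],
            matrix.taxa,
            np.vstack([matrix.codes, matrix.codes]),
        )
        c1 = pr.branch_change_counts(amniote, matrix)
        c2 = pr.branch_change_counts(amniote, doubled)
        for col in ("unambiguous_gains", "unambiguous_losses",
                    "possible_gains", "possible_losses"):
            assert (c2[col] == 2 * c1[col]).all()

    def test_annotated_newick_round_trips_with_lengths(self, five_taxon_tree):
        matrix = pr.CharacterMatrix.from_strings(
            ["g"], list("ABCDE"), [list("11100")])
        counts = pr.branch_change_counts(five_taxon_tree, matrix)
        nwk = pr.annotated_newick(five_taxon_tree, counts)
        assert "N2:1" in nwk.replace(".0", "")
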