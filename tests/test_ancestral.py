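"""Parsimony reconstruction, ACCTRAN/DELTRAN, Brownian motion, transitions."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from cladelink import (
    ACCTRAN,
    DELTRAN,
    CostMatrix,
    bm_ancestral,
    fitch,
    parse_newick,
    phylogeo_transitions,
    resolve,
    sankoff,
    simulate_bm,
    simulate_discrete,
)
from cladelink.simulate import SimConfig, generate_tree

from conftest import brute_force_parsimony, random_tree


def count_changes(tree, resolved):
    return sum(
        resolved[n.parent.id] != resolved[n.id]
        for n in tree.nodes
        if n.parent is not None
    )


def random_character(tree, seed, k=3):
    rng = np.random.default_rng(seed)
    states = ["X", "Y", "Z"][:k]
    return {l: states[int(rng.integers(k))] for l in tree.leaf_labels}


class TestFitch:
    def test_one_change_on_central_edge(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch(tree, {"A": "X", "B": "X", "C": "Y", "D": "Y"}).score == 1

    def test_constant_character_zero_changes(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch(tree, {l: "X" for l in "ABCD"}).score == 0

    def test_incongruent_character_two_changes(self):
        tree = parse_newick("((A,B),(C,D));")
        chr_map = {"A": "X", "B": "Y", "C": "X", "D": "Y"}
        pars = fitch(tree, chr_map)
        assert pars.score == 2
        assert pars.score == brute_force_parsimony(tree, chr_map)[0]

    def test_missing_leaf_state_listed(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="C"):
            fitch(tree, {"A": "X", "B": "X", "D": "Y"})

    def test_polytomy_hartigan(self):
        tree = parse_newick("(A,B,C,D);")
        chr_map = {"A": "X", "B": "X", "C": "Y", "D": "Z"}
        pars = fitch(tree, chr_map)
        assert pars.score == brute_force_parsimony(tree, chr_map)[0] == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_exhaustive_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(seed, int(rng.integers(4, 9)))
        chr_map = random_character(tree, seed + 1, k=int(rng.integers(2, 4)))
        score, optimal = brute_force_parsimony(tree, chr_map)
        pars = fitch(tree, chr_map)
        assert pars.score == score
        assert pars.optimal_states == optimal


class TestSankoff:
    def test_unit_cost_equals_fitch(self):
        for seed in range(10):
            tree = random_tree(seed + 100, 8)
            chr_map = random_character(tree, seed, k=3)
            states = sorted(set(chr_map.values()))
            assert sankoff(tree, chr_map, CostMatrix.unit(states)).score == fitch(
                tree, chr_map
            ).score

    def test_linear_cost_two_leaves(self):
        tree = parse_newick("(A,B);")
        costs = CostMatrix.linear(["0", "1", "2"])
        pars = sankoff(tree, {"A": "0", "B": "2"}, costs)
        assert pars.score == 2
        # every root state is optimal: 0+2 == 1+1 == 2+0
        assert pars.optimal_states[tree.root.id] == {"0", "1", "2"}

    def test_linear_matches_brute_force(self):
        tree = random_tree(3, 6)
        rng = np.random.default_rng(9)
        chr_map = {l: str(int(rng.integers(3))) for l in tree.leaf_labels}
        costs = CostMatrix.linear(["0", "1", "2"])
        cost_fn = lambda a, b: abs(int(a) - int(b))
        score, optimal = brute_force_parsimony(tree, chr_map, cost=cost_fn)
        pars = sankoff(tree, chr_map, costs)
        assert pars.score == pytest.approx(score)
        assert pars.optimal_states == optimal

    def test_single_leaf_zero(self):
        tree = parse_newick("A;")
        pars = sankoff(tree, {"A": "0"}, CostMatrix.linear(["0", "1"]))
        assert pars.score == 0

    def test_state_missing_from_matrix(self):
        tree = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="missing"):
            sankoff(tree, {"A": "X", "B": "Q"}, CostMatrix.unit(["X", "Y"]))

    def test_asymmetric_requires_flag(self):
        with pytest.raises(ValueError, match="symmetric"):
            CostMatrix(["a", "b"], [[0, 1], [2, 0]])
        CostMatrix(["a", "b"], [[0, 1], [2, 0]], symmetric=False)


class TestResolve:
    def test_unambiguous_reconstruction_rules_agree(self):
        tree = parse_newick("((A,B),(C,D));")
        chr_map = {"A": "X", "B": "X", "C": "Y", "D": "Y"}
        pars = fitch(tree, chr_map)
        acc = resolve(tree, pars, ACCTRAN)
        delt = resolve(tree, pars, DELTRAN)
        # interior assignment is ambiguous only at the root here
        assert count_changes(tree, acc) == count_changes(tree, delt) == 1

    def test_leaves_keep_observed_states(self):
        tree = parse_newick("((A,B),(C,D));")
        chr_map = {"A": "X", "B": "Y", "C": "X", "D": "Y"}
        pars = fitch(tree, chr_map)
        for rule in (ACCTRAN, DELTRAN):
            resolved = resolve(tree, pars, rule)
            for leaf in tree.leaves:
                assert resolved[leaf.id] == chr_map[leaf.label]

    def test_acctran_changes_earlier_than_deltran(self):
        # ((A,B,C),D) with A=B=Y, C=D=X: the ABC ancestor ties between keeping
        # the root's X (two changes on pendant edges) and switching to Y (one
        # change on its own edge plus one on C).  DELTRAN keeps the parent's
        # state, pushing both changes tipward; ACCTRAN changes immediately.
        tree = parse_newick("((A,B,C),D);")
        chr_map = {"A": "Y", "B": "Y", "C": "X", "D": "X"}
        pars = fitch(tree, chr_map)
        abc = tree.root.children[0]
        acc = resolve(tree, pars, ACCTRAN)
        delt = resolve(tree, pars, DELTRAN)
        assert count_changes(tree, acc) == count_changes(tree, delt) == pars.score == 2
        assert delt[abc.id] == delt[tree.root.id] == "X"
        assert acc[abc.id] == "Y"  # change pulled onto the edge nearest the root

    @pytest.mark.parametrize("rule", [ACCTRAN, DELTRAN])
    @pytest.mark.parametrize("seed", range(15))
    def test_resolution_is_optimal_and_uses_optimal_states(self, rule, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(seed + 300, int(rng.integers(4, 9)))
        chr_map = random_character(tree, seed + 7, k=3)
        score, optimal = brute_force_parsimony(tree, chr_map)
        pars = fitch(tree, chr_map)
        resolved = resolve(tree, pars, rule)
        assert count_changes(tree, resolved) == score
        for nid, state in resolved.items():
            assert state in optimal[nid]

    def test_deterministic_tie_breaks(self):
        tree = parse_newick("(A,B);")
        pars = fitch(tree, {"A": "X", "B": "Y"})
        assert resolve(tree, pars, DELTRAN)[tree.root.id] == "X"  # lexicographic


class TestBrownianMotion:
    def test_symmetric_two_leaf_root(self):
        result = bm_ancestral(parse_newick("(A:1,B:1);"), {"A": 0.0, "B": 2.0})
        assert result.root_value == pytest.approx(1.0)

    def test_weighted_two_leaf_root_and_numeric_likelihood(self):
        """Root ML value is the 1/branch-length weighted mean — confirmed by
        maximizing the exact bivariate normal likelihood numerically."""
        result = bm_ancestral(parse_newick("(A:1,B:3);"), {"A": 0.0, "B": 2.0})
        assert result.root_value == pytest.approx(0.5)

        def nll(mu):
            # leaves are independent N(mu, sigma2 * depth) given the root
            return -(
                norm.logpdf(0.0, mu, math.sqrt(1.0)) + norm.logpdf(2.0, mu, math.sqrt(3.0))
            )

        opt = minimize_scalar(nll, bounds=(-5, 5), method="bounded")
        assert result.root_value == pytest.approx(opt.x, abs=1e-4)

    def test_constant_character(self):
        tree = random_tree(5, 10)
        result = bm_ancestral(tree, {l: 3.25 for l in tree.leaf_labels})
        assert all(v == pytest.approx(3.25) for v in result.values.values())
        assert result.sigma2_hat == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_root_is_arithmetic_mean(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        values = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 10.0}
        result = bm_ancestral(tree, values)
        assert result.root_value == pytest.approx(np.mean(list(values.values())))

    def test_ancestral_values_within_leaf_range(self):
        for seed in range(5):
            tree = random_tree(seed + 40, 16)
            leaf_values, _ = simulate_bm(tree, sigma2=2.0, root_value=1.0, seed=seed)
            result = bm_ancestral(tree, leaf_values)
            lo, hi = min(leaf_values.values()), max(leaf_values.values())
            for v in result.values.values():
                assert lo - 1e-9 <= v <= hi + 1e-9

    def test_variances_positive_at_internals(self):
        tree = random_tree(8, 12)
        leaf_values, _ = simulate_bm(tree, sigma2=1.0, root_value=0.0, seed=2)
        result = bm_ancestral(tree, leaf_values)
        for node in tree.nodes:
            if node.is_leaf:
                assert result.variance[node.id] == 0.0
            else:
                assert result.variance[node.id] > 0.0

    def test_zero_length_pendant_floored_with_warning(self):
        tree = parse_newick("(A:0,B:1);")
        with pytest.warns(UserWarning, match="floored"):
            result = bm_ancestral(tree, {"A": 0.0, "B": 2.0})
        # root is pulled almost entirely to the zero-branch leaf
        assert result.root_value == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery(self):
        """Unbiased root estimates; sigma² recovered within 30% (median)."""
        tree = generate_tree(SimConfig(n_leaves=64, seed=1234))
        sigma2_true, root_true = 2.0, 5.0
        roots, sigma2s = [], []
        for rep in range(200):
            leaf_values, _ = simulate_bm(tree, sigma2_true, root_true, seed=rep)
            result = bm_ancestral(tree, leaf_values)
            roots.append(result.root_value)
            sigma2s.append(result.sigma2_hat)
        roots = np.asarray(roots)
        err = roots.mean() - root_true
        se = roots.std(ddof=1) / math.sqrt(len(roots))
        assert abs(err) <= 2 * se
        rel = np.abs(np.asarray(sigma2s) - sigma2_true) / sigma2_true
        assert np.median(rel) < 0.30


class TestTransitions:
    def test_two_leaf_transition_times(self):
        tree = parse_newick("(A:1,B:2);")
        resolved = {tree.root.id: "X", tree.leaf("A").id: "X", tree.leaf("B").id: "Y"}
        table = phylogeo_transitions(tree, resolved)
        flagged = table.transitions
        assert len(table.frame) == 2  # every edge listed
        assert len(flagged) == 1
        row = flagged.iloc[0]
        assert (row.parent_state, row.child_state) == ("X", "Y")
        assert (row.t_start, row.t_end) == (0.0, 2.0)

    def test_time_increments_equal_branch_lengths(self):
        tree = random_tree(77, 12)
        chr_map, _ = simulate_discrete(tree, ["P", "Q", "R"], rate=1.0, seed=3)
        resolved = resolve(tree, fitch(tree, chr_map), DELTRAN)
        table = phylogeo_transitions(tree, resolved)
        for row in table.frame.itertuples():
            child = tree.node(row.child)
            assert row.t_end - row.t_start == pytest.approx(child.parent_edge_length)

    def test_uniform_state_zero_flags(self):
        tree = parse_newick("(A:1,B:2);")
        resolved = {n.id: "X" for n in tree.nodes}
        assert len(phylogeo_transitions(tree, resolved).transitions) == 0

    def test_missing_gazetteer_entry_warns_not_fatal(self):
        tree = parse_newick("(A:1,B:2);")
        resolved = {tree.root.id: "X", tree.leaf("A").id: "X", tree.leaf("B").id: "Y"}
        with pytest.warns(UserWarning, match="Y"):
            table = phylogeo_transitions(tree, resolved, {"X": (10.0, 20.0)})
        assert table.missing_coordinates == ["Y"]
        assert len(table.frame) == 2

    def test_geojson_linestrings(self):
        import json

        tree = parse_newick("(A:1,B:2);")
        resolved = {tree.root.id: "X", tree.leaf("A").id: "X", tree.leaf("B").id: "Y"}
        gaz = {"X": (-33.45, -70.66), "Y": (-34.6, -58.38)}
        doc = json.loads(phylogeo_transitions(tree, resolved, gaz).to_geojson())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == 1
        feature = doc["features"][0]
        assert feature["geometry"]["coordinates"] == [[-70.66, -33.45], [-58.38, -34.6]]
        assert feature["properties"]["t_end"] == 2.0


class TestDiscreteRecovery:
    def test_root_state_recovered_in_majority_of_replicates(self):
        """Low-rate discrete character: parsimony finds the true root state
        more often than not (sanity property, not a calibration claim)."""
        tree = generate_tree(SimConfig(n_leaves=32, seed=99))
        hits = 0
        for rep in range(200):
            chr_map, true = simulate_discrete(
                tree, ["A", "B", "C"], rate=0.8, seed=10_000 + rep
            )
            resolved = resolve(tree, fitch(tree, chr_map), DELTRAN)
            hits += resolved[tree.root.id] == true[tree.root.id]
        assert hits / 200 > 0.5
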