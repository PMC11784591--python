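"""ARG tables, local trees, allele-state resolution and frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import argtrait as at
from argtrait.arg import ArgValidationError

from conftest import path_walk_states


class TestLoadArg:
    def test_fig1_tsv_round_trip_is_bit_identical(self, fig1, tmp_path):
        path = tmp_path / "fig1.tsv"
        at.write_arg(fig1, path)
        again = at.load_arg(path)
        assert fig1.equals(again)
        assert again.num_sites == 1
        assert len(again.mutations) == 2

    def test_random_arg_round_trip_is_bit_identical(self, tmp_path):
        arg = at.make_random_arg(20, 10, n_trees=2,
                                 stacked_mutation_rate=0.5, seed=42)
        assert arg.num_nodes >= 50
        path = tmp_path / "arg.tsv"
        at.write_arg(arg, path)
        assert arg.equals(at.load_arg(path))

    def test_zero_sites_is_valid(self):
        arg = at.make_random_arg(4, 0, seed=1)
        assert arg.num_sites == 0
        assert at.load_arg(arg) is not None

    def test_loads_from_text_and_file_object(self, fig1, tmp_path):
        path = tmp_path / "fig1.tsv"
        at.write_arg(fig1, path)
        text = path.read_text()
        assert at.load_arg(text).equals(fig1)
        with open(path) as f:
            assert at.load_arg(f).equals(fig1)

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError, match="no/such"):
            at.load_arg("no/such/file.tsv")

    def test_malformed_table_names_offending_content(self, fig1, tmp_path):
        path = tmp_path / "bad.tsv"
        at.write_arg(fig1, path)
        path.write_text(path.read_text().replace("#edges", "#bogus"))
        with pytest.raises(at.ArgParseError, match="bogus"):
            at.load_arg(path)

    def test_invariant_violation_names_rule(self, fig1, tmp_path):
        # make a parent younger than its child
        bad = fig1
        bad.nodes.loc[10, "time"] = 0.0  # root k below its children
        with pytest.raises(ArgValidationError, match="parent time"):
            at.load_arg(bad)

    def test_overlapping_edges_for_one_child_rejected(self, fig1):
        fig1.edges.loc[len(fig1.edges)] = [0.0, 50.0, 10, 0]
        with pytest.raises(ArgValidationError, match="overlap"):
            at.load_arg(fig1)

    def test_tskit_conversion_preserves_logical_content(self):
        tskit = pytest.importorskip("tskit")
        arg = at.make_random_arg(16, 6, n_trees=2,
                                 stacked_mutation_rate=0.4, seed=5)
        back = at.from_tree_sequence(at.to_tree_sequence(arg))
        # tskit canonicalises edge order; states and frequencies must agree
        for s in range(arg.num_sites):
            assert at.resolve_states(arg, s).state == at.resolve_states(back, s).state


class TestTreeAt:
    def test_single_tree_arg_is_position_independent(self):
        arg = at.make_random_arg(8, 2, n_trees=1, seed=2)
        t1 = at.tree_at(arg, 0.0)
        t2 = at.tree_at(arg, arg.sequence_length / 2)
        assert np.array_equal(t1.parent, t2.parent)

    def test_distinct_trees_across_breakpoint(self, ):
        arg = at.make_random_arg(10, 0, n_trees=2, seed=3)
        # breakpoint at 100 by construction
        left_tree = at.tree_at(arg, 99.9)
        right_tree = at.tree_at(arg, 100.0)
        assert not np.array_equal(left_tree.parent, right_tree.parent)

    def test_piecewise_constant_between_breakpoints(self):
        arg = at.make_random_arg(12, 0, n_trees=3, seed=9)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.uniform(0, arg.sequence_length)
            tree = at.tree_at(arg, pos)
            lo, hi = tree.interval
            other = at.tree_at(arg, rng.uniform(lo, hi))
            assert np.array_equal(tree.parent, other.parent)

    def test_fig1_topology(self, fig1):
        tree = at.tree_at(fig1, 50.0)
        # root k (10) above everything; i (8) above h (7) and j (9)
        assert tree.parent[8] == 10
        assert sorted(tree.children[8]) == [7, 9]
        assert tree.root_path(4) == [4, 9, 8, 10]

    def test_position_out_of_range(self, fig1):
        with pytest.raises(ValueError, match="outside"):
            at.tree_at(fig1, fig1.sequence_length)


class TestResolveStates:
    def test_no_mutations_gives_ancestral_everywhere(self):
        arg = at.make_random_arg(6, 0, seed=1)
        arg.sites.loc[0] = [0, 10.0, "G"]
        states = at.resolve_states(arg, 0).state
        assert set(states.values()) == {"G"}

    def test_fig1_back_mutation(self, fig1):
        states = at.resolve_states(fig1, 0).state
        # nodes below i carry T, except e (node 4) which reverts to A
        assert {u for u, s in states.items() if s == "T"} == {2, 3, 5, 7, 8, 9}
        assert states[4] == "A"
        assert states[10] == "A"  # root above the mutation

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_walk_oracle_with_stacked_mutations(self, seed):
        arg = at.make_random_arg(30, 5, n_trees=2,
                                 stacked_mutation_rate=0.8, seed=seed)
        for site in range(arg.num_sites):
            assert at.resolve_states(arg, site).state == \
                path_walk_states(arg, site)

    def test_ambiguous_stacked_mutations_rejected(self, fig1):
        # two mutations on one node, no parent link, no times
        fig1.mutations.loc[1] = [1, 0, 8, "G", -1, float("nan")]
        fig1.mutations.loc[0, "time"] = float("nan")
        with pytest.raises(ArgValidationError, match="ordered"):
            at.resolve_states(fig1, 0)


class TestAlleleFrequency:
    def test_ancestral_frequency_is_one_without_mutations(self):
        arg = at.make_random_arg(6, 0, seed=1)
        arg.sites.loc[0] = [0, 10.0, "C"]
        assert at.allele_frequency(arg, 0, "C") == 1.0

    def test_fig1_causal_allele_frequency(self, fig1):
        assert at.allele_frequency(fig1, 0, "T") == 0.5
        assert at.allele_frequency(fig1, 0, "A") == 0.5

    def test_absent_allele_has_zero_frequency(self, fig1):
        assert at.allele_frequency(fig1, 0, "G") == 0.0

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_frequencies_sum_to_one_over_alleles(self, seed):
        arg = at.make_random_arg(12, 3, stacked_mutation_rate=0.7, seed=seed)
        for site in range(arg.num_sites):
            alleles = set(arg.mutations.loc[
                arg.mutations["site"] == site, "derived_state"])
            alleles.add(str(arg.sites["ancestral_state"].iloc[site]))
            total = sum(at.allele_frequency(arg, site, a) for a in alleles)
            assert total == pytest.approx(1.0)
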