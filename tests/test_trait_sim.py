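"""Causal-site selection, allele choice and frequency-dependent scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import argtrait as at
from argtrait.trait_sim import eligible_alleles, eligible_sites


@pytest.fixture(scope="module")
def arg5():
    """Small single-tree ARG with 5 eligible sites."""
    return at.make_random_arg(10, 5, n_trees=1, seed=21)


class TestSelectCausalSites:
    def test_exhaustive_selection_returns_all_sites(self, arg5):
        pool = eligible_sites(arg5)
        assert at.select_causal_sites(arg5, len(pool), rng=0) == pool

    def test_single_site_arg_returns_it(self, fig1):
        assert at.select_causal_sites(fig1, 1, rng=0) == [0]

    def test_too_many_requested_reports_both_counts(self, arg5):
        with pytest.raises(ValueError, match="6.*5|5.*6"):
            at.select_causal_sites(arg5, 6)

    def test_selection_is_uniform(self, arg5):
        """Empirical single-site selection frequencies within 4 multinomial
        SEs of 1/5 over many repetitions."""
        reps = 10_000
        rng = np.random.default_rng(17)
        counts = np.zeros(5)
        for _ in range(reps):
            counts[at.select_causal_sites(arg5, 1, rng)[0]] += 1
        freq = counts / reps
        se = np.sqrt(0.2 * 0.8 / reps)
        assert np.all(np.abs(freq - 0.2) < 4 * se)

    def test_sorted_by_position(self, arg5):
        for seed in range(10):
            sites = at.select_causal_sites(arg5, 3, seed)
            positions = arg5.sites["position"].iloc[sites].to_numpy()
            assert np.all(np.diff(positions) > 0)


class TestChooseCausalAllele:
    def test_single_derived_allele_is_chosen(self, fig1):
        assert at.choose_causal_allele(fig1, 0, rng=0) == "T"

    def test_triallelic_site_alleles_equiprobable(self):
        # build a site with two segregating derived alleles
        arg = at.make_random_arg(10, 1, n_trees=1, seed=33)
        alleles = eligible_alleles(arg, 0)
        if len(alleles) < 2:
            tree = at.tree_at(arg, float(arg.sites["position"].iloc[0]))
            first = arg.mutations.iloc[0]
            taken = {str(first["derived_state"]),
                     str(arg.sites["ancestral_state"].iloc[0])}
            other = next(a for a in "ACGT" if a not in taken)
            # put the second allele on a disjoint non-root branch
            carriers = at.carrier_nodes(arg, 0, str(first["derived_state"]))
            candidates = [
                u for u in range(arg.num_nodes)
                if tree.parent[u] != -1 and not carriers[u]
                and arg.nodes["is_sample"].iloc[u] == 1
            ]
            arg.mutations.loc[len(arg.mutations)] = [
                1, 0, candidates[0], other, -1, 0.1]
            arg._cache.clear()
            alleles = eligible_alleles(arg, 0)
        assert len(alleles) >= 2
        names = [a for a, _ in alleles][:2]
        reps = 10_000
        rng = np.random.default_rng(3)
        hits = sum(at.choose_causal_allele(arg, 0, rng) == names[0]
                   for _ in range(reps))
        se = np.sqrt(0.25 / reps)
        assert abs(hits / reps - 1 / len(alleles)) < 4 * se

    def test_fixed_derived_allele_is_ineligible(self):
        # mutation above the root path of every sample: p = 1
        arg = at.make_fig1()
        arg.mutations.drop(index=1, inplace=True)
        arg.mutations.loc[0, "node"] = 10  # on the root: all samples inherit T
        arg._cache.clear()
        # every sample carries T -> p=1 -> not eligible
        assert at.allele_frequency(arg, 0, "T") == 1.0
        with pytest.raises(ValueError, match="segregating"):
            at.choose_causal_allele(arg, 0)


class TestFrequencyScale:
    @pytest.mark.parametrize("beta, p, alpha, expected", [
        (0.05, 0.3, 0.0, 0.05),            # alpha = 0 identity
        (1.0, 0.5, 2.0, 0.5),              # (2*0.5*0.5)^1
        (1.0, 0.5, -1.0, np.sqrt(2.0)),    # (0.5)^(-1/2)
    ])
    def test_closed_forms(self, beta, p, alpha, expected):
        assert at.frequency_scale(beta, p, alpha) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_frequencies_rejected(self, p):
        with pytest.raises(ValueError, match="frequency"):
            at.frequency_scale(1.0, p, -1.0)

    def test_alpha_sign_controls_rare_variant_weighting(self):
        """The scaling ratio depends only on p(1-p): decreasing in it for
        alpha < 0 (rare variants up-weighted), increasing for alpha > 0."""
        grid = np.linspace(0.05, 0.5, 10)  # p(1-p) increasing on (0, 0.5]
        for alpha in (-2.0, -0.5, 0.5, 2.0):
            ratio = np.array([at.frequency_scale(1.0, p, alpha) for p in grid])
            diffs = np.diff(ratio)
            assert np.all(diffs < 0) if alpha < 0 else np.all(diffs > 0)

    @given(st.floats(0.01, 0.99), st.floats(-3, 3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mirror_frequencies_scale_identically(self, p, alpha):
        assert at.frequency_scale(1.0, p, alpha) == pytest.approx(
            at.frequency_scale(1.0, 1.0 - p, alpha))


class TestSimTrait:
    def test_fig1_fixed_effect(self, fig1):
        table = at.sim_trait(fig1, at.trait_model("fixed", value=0.05),
                             alpha=0.0, random_seed=1)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["site_id"], row["causal_allele"]) == (0, "T")
        assert row["raw_beta"] == 0.05
        assert row["scaled_beta"] == 0.05
        assert row["allele_freq"] == 0.5

    def test_scaled_equals_raw_when_alpha_zero(self, arg5):
        table = at.sim_trait(arg5, "normal", num_causal=5, alpha=0.0,
                             random_seed=2)
        assert np.array_equal(table["raw_beta"], table["scaled_beta"])

    def test_explicit_site_list_passes_through(self, arg5):
        table = at.sim_trait(arg5, "normal", causal_sites=[0, 2, 4],
                             random_seed=3)
        assert list(table["site_id"]) == [0, 2, 4]
        expected = arg5.sites["position"].iloc[[0, 2, 4]].to_numpy()
        assert np.array_equal(table["position"], expected)

    def test_explicit_sites_with_fixed_betas(self, arg5):
        spec = pd.DataFrame({
            "position": arg5.sites["position"].iloc[[1, 3]],
            "raw_beta": [0.1, -0.2],
        })
        table = at.sim_trait(arg5, "normal", causal_sites=spec, alpha=0.0,
                             random_seed=4)
        assert list(table["raw_beta"]) == [0.1, -0.2]

    def test_pleiotropic_model_shares_sites_across_traits(self, arg5):
        model = at.trait_model("multivariate-normal", mean=[0, 0],
                               cov=[[1, 0.5], [0.5, 1]])
        table = at.sim_trait(arg5, model, num_causal=4, random_seed=5)
        assert len(table) == 8
        by_trait = {t: sorted(g["site_id"]) for t, g in table.groupby("trait_id")}
        assert by_trait[0] == by_trait[1]
        assert len(by_trait[0]) == 4

    def test_row_count_is_sites_times_traits(self, arg5):
        model = at.trait_model("multivariate-normal",
                               mean=[0, 0, 0], cov=np.eye(3).tolist())
        table = at.sim_trait(arg5, model, num_causal=5, random_seed=6)
        assert len(table) == 15

    def test_explicit_and_random_paths_agree_when_sites_coincide(self, arg5):
        seed = 8
        random_path = at.sim_trait(arg5, "normal", num_causal=3,
                                   alpha=-1.0, random_seed=seed)
        explicit = at.sim_trait(arg5, "normal",
                                causal_sites=list(random_path["site_id"]),
                                alpha=-1.0, random_seed=seed)
        pd.testing.assert_frame_equal(random_path, explicit)
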