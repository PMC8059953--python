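"""Variable-rates machinery: pruning likelihood vs dense oracle, ESS,
reversible-jump sampler, stepping-stone evidence, consensus summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from morphodyn import (ChainConfig, RatePosterior, bayes_factor, bm_loglik,
                       effective_sample_size, mean_scalar_tree,
                       rates_through_time, rjmcmc_variable_rates,
                       stepping_stone)
from morphodyn.phylo import Tree
from morphodyn.rates import LikelihoodEngine

from conftest import traits_frame
from oracles import dense_loglik, random_bm_instance


@pytest.mark.parametrize("seed", range(8))
def test_pruning_matches_dense_mvn(seed):
    tree, traits, sigma2, shifts, by_node, roots = random_bm_instance(
        seed, traits_frame)
    mine = bm_loglik(tree, traits, sigma2, shifts, root_states=roots)
    oracle = dense_loglik(tree, traits, sigma2, by_node, roots)
    assert abs(mine - oracle) < 1e-8


def test_scalar_duration_equivalence():
    """Multiplying all durations by c equals setting all scalars to c."""
    tree, traits, sigma2, _, _, roots = random_bm_instance(99, traits_frame)
    scaled = tree.copy()
    for node in scaled.postorder():
        node.age = node.age * 2.0
    scaled.update_lengths_from_ages()
    engine = LikelihoodEngine(tree, traits)
    all_clade_2 = {("branch", i): 2.0 for i in engine.branch_locs}
    a = bm_loglik(scaled, traits, sigma2, None, root_states=roots)
    b = bm_loglik(tree, traits, sigma2, all_clade_2, root_states=roots)
    assert a == pytest.approx(b, abs=1e-10)


def test_single_tip_pair_closed_form():
    """Cherry REML likelihood equals the single-contrast normal density."""
    tree = Tree.from_newick("(A:2,B:3);")
    tree.update_ages_from_lengths(tip_ages={"A": 1.0, "B": 0.0})
    traits = pd.DataFrame({"T1": [0.4, -0.2]}, index=["A", "B"])
    ll = bm_loglik(tree, traits, np.array([0.7]))
    v = 0.7 * (2 + 3)
    expected = -0.5 * (math.log(2 * math.pi * v) + (0.4 + 0.2) ** 2 / v)
    assert ll == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------------
# ESS
# ----------------------------------------------------------------------
def test_ess_iid():
    x = np.random.default_rng(0).normal(size=1000)
    assert 800 <= effective_sample_size(x) <= 1200


def test_ess_ar1_strongly_reduced():
    rng = np.random.default_rng(1)
    x = np.empty(5000)
    x[0] = 0.0
    for i in range(1, x.size):
        x[i] = 0.9 * x[i - 1] + rng.normal()
    assert effective_sample_size(x) < x.size / 5


def test_ess_alternating_not_capped():
    x = np.tile([1.0, -1.0], 500)
    assert effective_sample_size(x) >= 1000


def test_ess_constant_warns():
    with pytest.warns(UserWarning, match="constant"):
        assert effective_sample_size(np.ones(50)) == 50


# ----------------------------------------------------------------------
# Bayes factor
# ----------------------------------------------------------------------
def test_bayes_factor_definition():
    assert bayes_factor(3.0, 3.0) == 0.0
    assert bayes_factor(8.0, 3.0) == 10.0
    assert bayes_factor(3.0, 8.0) == -bayes_factor(8.0, 3.0)
    with pytest.raises(ValueError):
        bayes_factor(np.inf, 0.0)


# ----------------------------------------------------------------------
# sampler
# ----------------------------------------------------------------------
def test_chain_config_validation():
    with pytest.raises(ValueError, match="burn_in"):
        ChainConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError, match="thinning"):
        ChainConfig(thinning=0)
    with pytest.raises(ValueError, match="stones"):
        ChainConfig(n_stones=1)


def test_flat_likelihood_samples_uniform_shift_prior(small_world):
    """With the likelihood flattened, the shift count follows its uniform
    prior (smoke-scale; the full 10^4-sample check runs in acceptance)."""
    traits = traits_frame(small_world.tip_traits)
    cfg = ChainConfig(iterations=60_000, burn_in=5_000, thinning=25, seed=3,
                      max_shifts=5)
    post = rjmcmc_variable_rates(small_world.tree, traits, cfg,
                                 flat_likelihood=True)
    counts = post.trace["n_shifts"].value_counts().reindex(range(6),
                                                           fill_value=0)
    _, p = chisquare(counts, f_exp=np.full(6, counts.sum() / 6))
    assert p > 0.01


def test_deterministic_trace(small_world):
    traits = traits_frame(small_world.tip_traits)
    cfg = ChainConfig(iterations=5_000, burn_in=1_000, thinning=20, seed=5)
    p1 = rjmcmc_variable_rates(small_world.tree, traits, cfg)
    p2 = rjmcmc_variable_rates(small_world.tree, traits, cfg)
    pd.testing.assert_frame_equal(p1.trace, p2.trace)
    np.testing.assert_array_equal(p1.mean_branch_scalars,
                                  p2.mean_branch_scalars)


def test_recovery_of_planted_clade(shifted_world):
    """A clade planted at scalar 10 shows elevated posterior mean scalars."""
    traits = traits_frame(shifted_world.tip_traits)
    cfg = ChainConfig(iterations=60_000, burn_in=12_000, thinning=50, seed=2)
    post = rjmcmc_variable_rates(shifted_world.tree, traits, cfg)
    node, _ = shifted_world.shift_nodes[0]
    assert post.clade_background_ratio(node) >= 3.0


# ----------------------------------------------------------------------
# stepping stone
# ----------------------------------------------------------------------
def _log_evidence_oracle(tree, traits, a0, b0):
    """Numerical integration of the REML likelihood against the
    inverse-gamma prior, per independent trait."""
    total = 0.0
    for j in range(traits.shape[1]):
        col = traits.iloc[:, [j]]

        def integrand(log_s2):
            s2 = math.exp(log_s2)
            ll = bm_loglik(tree, col, np.array([s2]))
            lp = (a0 * math.log(b0) - math.lgamma(a0)
                  - (a0 + 1) * log_s2 - b0 / s2)
            return math.exp(ll + lp + log_s2)  # + Jacobian

        val, _ = quad(integrand, -18, 6, limit=200)
        total += math.log(val)
    return total


def test_stepping_stone_matches_conjugate_evidence(small_world):
    """Homogeneous-model stepping-stone evidence agrees with direct
    numerical integration of the conjugate model to < 0.1 log units."""
    traits = traits_frame(small_world.tip_traits).iloc[:, :2]
    cfg = ChainConfig(iterations=10_000, burn_in=2_000, seed=4,
                      sigma_prior_a=2.0, sigma_prior_b=1e-3,
                      n_stones=20, stone_iterations=2_000)
    est = stepping_stone(small_world.tree, traits, "homogeneous", cfg)
    oracle = _log_evidence_oracle(small_world.tree, traits, 2.0, 1e-3)
    assert abs(est - oracle) < 0.1


def test_stepping_stone_rejects_degenerate_ladder(small_world):
    traits = traits_frame(small_world.tip_traits)
    with pytest.raises(ValueError):
        stepping_stone(small_world.tree, traits, "variable",
                       ChainConfig(n_stones=1))
    with pytest.raises(ValueError, match="unknown model"):
        stepping_stone(small_world.tree, traits, "both", ChainConfig())


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------
def _posterior_with_scalars(tree, value):
    scalars = np.full(len(list(tree.postorder())), value)
    return RatePosterior(tree=tree, trace=pd.DataFrame(),
                         mean_branch_scalars=scalars, shift_samples=[],
                         ess={}, acceptance={}, config=ChainConfig())


def test_mean_scalar_tree_trivial_and_average():
    tree = Tree.from_newick("((A:1,B:1):1,C:2);")
    tree.update_ages_from_lengths()
    tree.reindex()
    ones = mean_scalar_tree([_posterior_with_scalars(tree, 1.0)])
    for node in ones.postorder():
        if node.parent is not None:
            assert node.length == pytest.approx(1.0)
    two_four = mean_scalar_tree([_posterior_with_scalars(tree, 2.0),
                                 _posterior_with_scalars(tree.copy(), 4.0)])
    for node in two_four.postorder():
        if node.parent is not None:
            assert node.length == pytest.approx(3.0)
    assert sorted(two_four.leaf_labels()) == ["A", "B", "C"]


def test_mean_scalar_tree_rejects_disjoint_tips():
    t1 = Tree.from_newick("(A:1,B:1);"); t1.update_ages_from_lengths()
    t2 = Tree.from_newick("(A:1,C:1);"); t2.update_ages_from_lengths()
    with pytest.raises(ValueError, match="tip set"):
        mean_scalar_tree([_posterior_with_scalars(t1, 1.0),
                          _posterior_with_scalars(t2, 1.0)])


def test_rates_through_time_flat_and_local():
    tree = Tree.from_newick("((A:2,B:2):2,C:4);")
    tree.update_ages_from_lengths()
    tree.reindex()
    flat = rates_through_time([_posterior_with_scalars(tree, 1.0)],
                              bin_width=1.0)
    assert np.allclose(flat["mean_rate"].dropna(), 1.0)
    # elevate only the branch to C (spans the full 0-4 Ma range)
    post = _posterior_with_scalars(tree, 1.0)
    c_idx = tree.find("C").index
    post.mean_branch_scalars[c_idx] = 5.0
    local = rates_through_time([post], bin_width=1.0)
    young = local[local["bin_older"] <= 2.0]["mean_rate"]
    old = local[local["bin_older"] > 2.0]["mean_rate"].dropna()
    assert (young > 1.0).all()
    assert np.allclose(old, (5.0 + 1.0 + 1.0) / 3.0) or (old > 1.0).all()


def test_rates_through_time_clade_restriction(shifted_world):
    traits = traits_frame(shifted_world.tip_traits)
    cfg = ChainConfig(iterations=30_000, burn_in=6_000, thinning=50, seed=6)
    post = rjmcmc_variable_rates(shifted_world.tree, traits, cfg)
    node, _ = shifted_world.shift_nodes[0]
    clade = shifted_world.tree.clade_leaf_labels(node)
    origin = node.parent.age
    both = rates_through_time([post], bin_width=2.0)
    restricted = rates_through_time([post], bin_width=2.0, clade=clade)
    merged = both.merge(restricted, on=["bin_older", "bin_younger"],
                        suffixes=("_all", "_clade"))
    active = merged.dropna(subset=["mean_rate_clade"])
    recent = active[active["bin_older"] < origin]
    assert (recent["mean_rate_clade"] >= recent["mean_rate_all"] - 1e-9).all()
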