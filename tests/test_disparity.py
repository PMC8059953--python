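"""Disparity metrics against independent oracles; binning, bootstrap,
ancestral states and time-slicing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphodyn import (TimeBins, alpha_shape_volume, ancestral_states,
                       bin_membership, bootstrap_ci, disparity_through_time,
                       lineage_values_at, mean_pairwise_distance, mst_length,
                       partial_disparity, rarefy_metric)
from morphodyn.phylo import Tree


from oracles import mpd_oracle, mst_oracle


# ----------------------------------------------------------------------
# MPD / MST
# ----------------------------------------------------------------------
def test_mpd_trivial_cases():
    assert mean_pairwise_distance(np.array([[0.0], [3.0]])) == pytest.approx(3.0)
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    assert mean_pairwise_distance(tri) == pytest.approx(1.0)
    assert np.isnan(mean_pairwise_distance(np.array([[1.0, 2.0]])))


def test_mpd_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        pts = rng.normal(size=(6, 3))
        assert mean_pairwise_distance(pts) == pytest.approx(mpd_oracle(pts),
                                                            rel=1e-12)


def test_mst_trivial_cases():
    assert mst_length(np.array([[0.0], [1.0], [2.0]])) == pytest.approx(2.0)
    square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
    assert mst_length(square) == pytest.approx(3.0)
    dup = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
    assert mst_length(dup) == pytest.approx(1.0)


def test_mst_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    for n in (4, 6, 7):
        pts = rng.normal(size=(n, 2))
        assert mst_length(pts) == pytest.approx(mst_oracle(pts), rel=1e-10)


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_metrics_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 3))
    perm = rng.permutation(8)
    assert mean_pairwise_distance(pts) == pytest.approx(
        mean_pairwise_distance(pts[perm]), rel=1e-12)
    assert mst_length(pts) == pytest.approx(mst_length(pts[perm]), rel=1e-10)


# ----------------------------------------------------------------------
# alpha shapes
# ----------------------------------------------------------------------
UNIT_TETRA = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                       [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])


def test_tetrahedron_closed_form():
    assert alpha_shape_volume(UNIT_TETRA, np.inf) == pytest.approx(
        np.sqrt(2) / 12, rel=1e-10)


def test_alpha_below_circumradius_gives_zero():
    # unit regular tetrahedron circumradius = sqrt(3/8)
    assert alpha_shape_volume(UNIT_TETRA, 0.5) == 0.0
    assert alpha_shape_volume(UNIT_TETRA, 1.0) == pytest.approx(
        np.sqrt(2) / 12, rel=1e-10)


def test_alpha_monotone_and_cluster_separation():
    rng = np.random.default_rng(2)
    cloud1 = rng.normal(0, 0.5, size=(20, 3))
    cloud2 = rng.normal(0, 0.5, size=(20, 3)) + 20.0
    pts = np.vstack([cloud1, cloud2])
    alphas = [1.0, 2.0, 5.0, 50.0, 1e6, np.inf]
    vols = [alpha_shape_volume(pts, a) for a in alphas]
    assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vols, vols[1:]))
    hull = alpha_shape_volume(pts, np.inf)
    small = alpha_shape_volume(pts, 3.0)
    assert 0 < small < hull
    assert vols[-2] == pytest.approx(hull, rel=1e-9)


def test_coplanar_gives_zero_volume():
    flat = np.column_stack([np.random.default_rng(3).normal(size=(10, 2)),
                            np.zeros(10)])
    assert alpha_shape_volume(flat, np.inf) == 0.0


# ----------------------------------------------------------------------
# partial disparity
# ----------------------------------------------------------------------
def test_partial_disparity_single_group_equals_total():
    rng = np.random.default_rng(4)
    scores = {f"t{i}": rng.normal(size=3) for i in range(10)}
    pd_map = partial_disparity(scores, {t: "all" for t in scores})
    x = np.array([scores[t] for t in sorted(scores)])
    total = ((x - x.mean(axis=0)) ** 2).sum() / (len(x) - 1)
    assert pd_map["all"] == pytest.approx(total, rel=1e-12)


def test_partial_disparity_symmetric_groups():
    scores = {"a": np.array([1.0, 0.0]), "b": np.array([-1.0, 0.0]),
              "c": np.array([0.0, 2.0]), "d": np.array([0.0, -2.0])}
    pd_map = partial_disparity(scores, {"a": "g1", "b": "g1",
                                        "c": "g2", "d": "g2"})
    assert pd_map["g1"] == pytest.approx(2.0 / 3.0)
    assert pd_map["g2"] == pytest.approx(8.0 / 3.0)


def test_partial_disparity_conservation():
    rng = np.random.default_rng(5)
    scores = {f"t{i}": rng.normal(size=4) for i in range(20)}
    groups = {t: f"g{rng.integers(3)}" for t in scores}
    pd_map = partial_disparity(scores, groups)
    x = np.array([scores[t] for t in sorted(scores)])
    total = ((x - x.mean(axis=0)) ** 2).sum() / (len(x) - 1)
    assert sum(pd_map.values()) == pytest.approx(total, abs=1e-12)


# ----------------------------------------------------------------------
# rarefaction & bootstrap
# ----------------------------------------------------------------------
def test_rarefy_partial_rule():
    pts = np.random.default_rng(6).normal(size=(5, 2))
    full = mean_pairwise_distance(pts)
    assert rarefy_metric(pts, 5, mean_pairwise_distance, 50, 0) == full
    assert rarefy_metric(pts, 10, mean_pairwise_distance, 50, 0) == full


def test_rarefied_mst_not_longer_than_full():
    pts = np.random.default_rng(7).normal(size=(10, 2))
    full = mst_length(pts)
    rare = rarefy_metric(pts, 5, mst_length, 200, seed=1)
    assert rare <= full + 1e-12


def test_bootstrap_degenerate_and_bounds():
    same = np.tile([[1.0, 2.0]], (6, 1))
    assert bootstrap_ci(same, mean_pairwise_distance, 100, seed=0) == (0.0, 0.0)
    two = np.array([[0.0], [1.0]])
    lo, hi = bootstrap_ci(two, mean_pairwise_distance, 500, seed=1)
    assert lo == 0.0 and hi <= 1.0


def test_bootstrap_coverage_of_population_mpd():
    """Nominal 95% percentile interval covers the population MPD of a
    2D Gaussian cloud in >= 90% of simulations."""
    pop_mpd = np.sqrt(np.pi)  # E||X-Y||, X,Y ~ N(0, I_2)
    rng = np.random.default_rng(8)
    covered = 0
    n_sim = 200
    for s in range(n_sim):
        pts = rng.normal(size=(100, 2))
        lo, hi = bootstrap_ci(pts, mean_pairwise_distance, n_boot=400, seed=s)
        covered += lo <= pop_mpd <= hi
    assert covered / n_sim >= 0.90


# ----------------------------------------------------------------------
# bins
# ----------------------------------------------------------------------
def _bins():
    return TimeBins(pd.DataFrame({"label": ["old", "young"],
                                  "older": [200.0, 150.0],
                                  "younger": [150.0, 100.0]}))


def test_bin_membership_rules():
    occ = pd.DataFrame({
        "taxon": ["inside", "spanning", "boundary", "outside"],
        "fad": [190.0, 160.0, 150.0, 50.0],
        "lad": [180.0, 140.0, 150.0, 40.0]})
    member = bin_membership(occ, _bins())
    assert member["old"] == {"inside", "spanning"}
    # FAD on a bin's older bound -> that bin only
    assert member["young"] == {"spanning", "boundary"}


def test_bins_validation():
    with pytest.raises(ValueError, match="overlap"):
        TimeBins(pd.DataFrame({"label": ["a", "b"], "older": [10.0, 6.0],
                               "younger": [5.0, 0.0]}))
    with pytest.raises(ValueError, match="older > younger"):
        TimeBins(pd.DataFrame({"label": ["a"], "older": [1.0],
                               "younger": [2.0]}))


# ----------------------------------------------------------------------
# ancestral states & slicing
# ----------------------------------------------------------------------
def test_ancestral_cherry_symmetric():
    tree = Tree.from_newick("(A:2,B:2);")
    tree.update_ages_from_lengths()
    anc = ancestral_states(tree, {"A": np.array([0.0]), "B": np.array([2.0])})
    assert anc[tree.root][0] == pytest.approx(1.0)


def test_ancestral_cherry_weighted(cherry):
    anc = ancestral_states(cherry, {"A": np.array([0.0]), "B": np.array([2.0])})
    assert anc[cherry.root][0] == pytest.approx(0.5)


def test_ancestral_constant_propagates(small_world):
    tips = {t: np.array([2.5]) for t in small_world.tree.leaf_labels()}
    anc = ancestral_states(small_world.tree, tips)
    for v in anc.values():
        assert v[0] == pytest.approx(2.5, abs=1e-9)


def test_ancestral_missing_taxon_named(cherry):
    with pytest.raises(ValueError, match="B"):
        ancestral_states(cherry, {"A": np.array([0.0])})


def test_lineage_values_models():
    tree = Tree.from_newick("(A:4,B:4);")
    tree.update_ages_from_lengths()
    tips = {"A": np.array([0.0]), "B": np.array([4.0])}
    anc = {tree.root: np.array([2.0])}
    # midpoint of both branches, gradual: halfway between endpoint values
    vals = sorted(v[0] for v in lineage_values_at(tree, tips, anc, 2.0, "gradual"))
    assert vals == [pytest.approx(1.0), pytest.approx(3.0)]
    vals_p = sorted(v[0] for v in lineage_values_at(tree, tips, anc, 2.0,
                                                    "punctuated-parent"))
    assert vals_p == [pytest.approx(2.0), pytest.approx(2.0)]
    # at a tip age, the observed value
    at_tip = lineage_values_at(tree, tips, anc, 0.0, "gradual")
    assert sorted(v[0] for v in at_tip) == [pytest.approx(0.0), pytest.approx(4.0)]
    # at the root age, the node estimate (all models agree)
    for model in ("gradual", "punctuated-parent", "punctuated-child"):
        at_root = lineage_values_at(tree, tips, anc, 4.0, model)
        assert [v[0] for v in at_root] == [pytest.approx(2.0)]
    with pytest.raises(ValueError, match="older than the root"):
        lineage_values_at(tree, tips, anc, 5.0)


def test_dtt_identical_tips_zero_and_identical_trees_identical(small_world):
    tree = small_world.tree
    tips = {t: np.array([1.0, 1.0]) for t in tree.leaf_labels()}
    times = np.linspace(tree.root.age * 0.9, 0.0, 5)
    series, summary = disparity_through_time([tree, tree], tips, times, "mpd")
    valid = series.dropna(subset=["value"])
    assert np.allclose(valid["value"], 0.0, atol=1e-9)
    s0 = series[series.tree_index == 0]["value"].to_numpy()
    s1 = series[series.tree_index == 1]["value"].to_numpy()
    np.testing.assert_array_equal(s0, s1)


def test_dtt_detects_planted_high_rate_clade(shifted_world):
    """Time-sliced MPD rises after the origin of a fast-evolving clade."""
    world = shifted_world
    node, _ = world.shift_nodes[0]
    origin = node.parent.age
    times = np.linspace(world.tree.root.age * 0.99, 0.0, 12)
    series, _ = disparity_through_time([world.tree], world.tip_traits, times,
                                       "mpd")
    before = series[series.time > origin]["value"].dropna()
    after = series[series.time < origin * 0.5]["value"].dropna()
    assert after.mean() > before.mean()


def test_time_sliced_present_equals_extant_within_bin_mpd(small_world):
    world = small_world
    extant = [leaf.label for leaf in world.tree.leaves() if leaf.age == 0.0]
    if len(extant) < 2:
        pytest.skip("world has < 2 extant tips")
    anc = ancestral_states(world.tree, world.tip_traits)
    sliced = lineage_values_at(world.tree, world.tip_traits, anc, 0.0)
    direct = np.array([world.tip_traits[t] for t in extant])
    assert mean_pairwise_distance(sliced) == pytest.approx(
        mean_pairwise_distance(direct), rel=1e-9)
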