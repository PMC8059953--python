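"""Time-calibration of fossil-tree topologies against occurrence data.

Implements the standard a-posteriori dating toolkit for supertrees of fossil
taxa: uniform random polytomy resolution, stochastic tip-age sampling from
first/last appearance (FAD/LAD) ranges, and three dating rules —

* ``equal``: node ages are initialised at the oldest descendant tip age, the
  root is pushed back by a configurable extension, and zero-length branches
  absorb time by sharing it equally along the chain up to the next older
  dated node;
* ``mbl``: minimum branch length — ancestors are pushed older, tips rootward,
  until every branch is at least the minimum;
* ``cal3``-style stochastic dating: node ages are drawn older than the oldest
  descendant first appearance with exponential waiting times whose rate is
  built from branching (p), extinction (q) and sampling (r) rates, so that
  better sampling collapses nodes toward the observed record.

Ensembles of dated trees (polytomy resolution x tip-age draw x dating) are
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Node, Tree


# ----------------------------------------------------------------------
# occurrence tables
# ----------------------------------------------------------------------
def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    """Check an occurrence table (columns taxon, fad, lad; Ma)."""
    required = {"taxon", "fad", "lad"}
    if not required.issubset(occ.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    if occ["taxon"].duplicated().any():
        dupes = occ.loc[occ["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"duplicate taxa in occurrence table: {dupes}")
    bad = occ[(occ["fad"] < occ["lad"]) | (occ["lad"] < 0)]
    if len(bad):
        raise ValueError(f"invalid FAD/LAD rows: {bad['taxon'].tolist()}")
    return occ


def read_occurrences(path) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(path))


# ----------------------------------------------------------------------
# polytomy resolution and tip ages
# ----------------------------------------------------------------------
def resolve_polytomies(tree: Tree, seed: int) -> Tree:
    """Replace every multifurcation by a uniformly random binary resolution.

    Each polytomy's child subtrees are reassembled by sequential attachment:
    subtrees are added one at a time at an edge chosen uniformly among the
    current edges (the stem included), which yields the uniform distribution
    over rooted binary topologies.  Branch lengths/ages of new nodes are left
    unset; dating happens downstream.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.postorder()):
        if len(node.children) <= 2:
            continue
        children = list(node.children)
        node.children = []
        for c in children:
            c.parent = None
        # build a random binary tree over the child subtrees
        current = children[0]
        edges = [current]  # nodes identifying the edge above them
        for sub in children[1:]:
            spot = edges[int(rng.integers(len(edges)))]
            joint = Node()
            parent = spot.parent
            if parent is not None:
                parent.children[parent.children.index(spot)] = joint
                joint.parent = parent
            joint.add_child(spot)
            joint.add_child(sub)
            if spot is current:
                current = joint
            edges.append(joint)
            edges.append(sub)
        node.add_child(current)
        if len(node.children) == 1:
            # the polytomy node now has a single child: splice it in
            only = node.children[0]
            node.children = only.children
            for c in node.children:
                c.parent = node
    out.reindex()
    return out


def sample_tip_ages(occ: pd.DataFrame, seed: int) -> dict[str, float]:
    """One age per taxon, Uniform[LAD, FAD] (degenerate ranges give the point)."""
    validate_occurrences(occ)
    rng = np.random.default_rng(seed)
    ages: dict[str, float] = {}
    for row in occ.itertuples(index=False):
        ages[row.taxon] = float(rng.uniform(row.lad, row.fad)) \
            if row.fad > row.lad else float(row.fad)
    return ages


def _check_tips_aged(tree: Tree, tip_ages: dict[str, float]) -> None:
    missing = [lab for lab in tree.leaf_labels() if lab not in tip_ages]
    if missing:
        raise ValueError(f"no occurrence ages for taxa: {sorted(missing)}")


def _initial_ages(tree: Tree, tip_ages: dict[str, float]) -> None:
    """Node ages = oldest descendant tip age (zero branches allowed)."""
    for node in tree.postorder():
        if node.is_leaf():
            node.age = float(tip_ages[node.label])
        else:
            node.age = max(c.age for c in node.children)


# ----------------------------------------------------------------------
# dating rules
# ----------------------------------------------------------------------
def timescale_equal(topology: Tree, tip_ages: dict[str, float],
                    root_extension: float = 10.0) -> Tree:
    """'equal' dating: share zero-length branch time equally up the chain."""
    tree = topology.copy()
    if not tree.is_binary():
        raise ValueError("equal dating requires a binary topology")
    _check_tips_aged(tree, tip_ages)
    _initial_ages(tree, tip_ages)
    if root_extension <= 0 and any(c.age >= tree.root.age for c in tree.root.children):
        raise ValueError("root_extension must be > 0 when a root child has "
                         "zero branch length")
    tree.root.age = tree.root.age + root_extension

    # preorder pass: each zero-length branch shares the time down from the
    # nearest strictly older ancestor equally along the chain
    for node in tree.preorder():
        if node.parent is None or node.age < node.parent.age:
            continue
        # walk up through ancestors at the same age
        chain = [node]
        anc = node.parent
        while anc.age <= node.age:
            chain.append(anc)
            anc = anc.parent
        # chain nodes between anc (exclusive) and node: space ages equally;
        # node itself keeps its age (tips are fixed; internal nodes are
        # raised later via their own descendants if needed)
        span = anc.age - node.age
        m = len(chain)  # number of branches from anc down to node
        for i, member in enumerate(reversed(chain[1:]), start=1):
            member.age = anc.age - span * i / m
    tree.update_lengths_from_ages()
    tree.validate_dated(tol=0.0)
    return tree


def timescale_mbl(topology: Tree, tip_ages: dict[str, float],
                  min_branch: float) -> Tree:
    """Minimum-branch-length dating: push ancestors older, tips rootward."""
    if min_branch <= 0:
        raise ValueError("min_branch must be > 0")
    tree = topology.copy()
    if not tree.is_binary():
        raise ValueError("mbl dating requires a binary topology")
    _check_tips_aged(tree, tip_ages)
    for node in tree.postorder():
        if node.is_leaf():
            node.age = float(tip_ages[node.label])
        else:
            node.age = max(c.age + min_branch for c in node.children)
    tree.update_lengths_from_ages()
    tree.validate_dated(tol=0.0)
    return tree


def timescale_cal3(topology: Tree, occ: pd.DataFrame,
                   cal3_rates: tuple[float, float, float],
                   seed: int, tip_ages: dict[str, float] | None = None) -> Tree:
    """Sampling-rate-calibrated stochastic dating.

    Node ages are drawn postorder: each node sits older than both its
    children and its oldest descendant first appearance by an
    Exponential(p - q + r) waiting time — branching (p) and sampling (r)
    shorten unobserved history, extinction (q) lengthens it.  As r grows,
    node ages collapse toward the oldest descendant FADs.
    """
    p, q, r = cal3_rates
    if min(p, q, r) <= 0:
        raise ValueError("cal3 rates (p, q, r) must all be > 0")
    rate = p - q + r
    if not np.isfinite(rate) or rate <= 0:
        raise ValueError(f"cal3 waiting-time rate p - q + r = {rate} is not positive")
    tree = topology.copy()
    if not tree.is_binary():
        raise ValueError("cal3 dating requires a binary topology")
    validate_occurrences(occ)
    rng = np.random.default_rng(seed)
    if tip_ages is None:
        tip_ages = sample_tip_ages(occ, int(rng.integers(2 ** 31)))
    _check_tips_aged(tree, tip_ages)
    fad = dict(zip(occ["taxon"], occ["fad"]))
    oldest_fad: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_leaf():
            node.age = float(tip_ages[node.label])
            oldest_fad[node] = float(fad[node.label])
        else:
            oldest_fad[node] = max(oldest_fad[c] for c in node.children)
            floor = max(max(c.age for c in node.children), oldest_fad[node])
            node.age = floor + rng.exponential(1.0 / rate)
    tree.update_lengths_from_ages()
    tree.validate_dated(tol=0.0)
    return tree


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------
@dataclass
class CalibrationConfig:
    """Settings for building an ensemble of dated trees."""

    method: str = "equal"                 # equal | mbl | cal3
    min_branch: float = 1.0               # mbl, Myr
    root_extension: float = 10.0          # equal, Myr
    cal3_rates: tuple[float, float, float] = (0.1, 0.1, 0.5)  # per Myr
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("equal", "mbl", "cal3"):
            raise ValueError(f"unknown dating method {self.method!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.method == "mbl" and self.min_branch <= 0:
            raise ValueError("mbl requires min_branch > 0")
        if self.method == "equal" and self.root_extension <= 0:
            raise ValueError("equal requires root_extension > 0")
        if self.method == "cal3" and min(self.cal3_rates) <= 0:
            raise ValueError("cal3 requires positive (p, q, r)")


def make_one(topology: Tree, occ: pd.DataFrame, config: CalibrationConfig,
             index: int) -> Tree:
    """Tree ``index`` of the ensemble, reproducible from (config.seed, index)."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(index,))
    s_resolve, s_ages, s_date = (int(c.generate_state(1)[0] % (2 ** 31))
                                 for c in ss.spawn(3))
    binary = resolve_polytomies(topology, s_resolve)
    tip_ages = sample_tip_ages(occ, s_ages)
    if config.method == "equal":
        return timescale_equal(binary, tip_ages, config.root_extension)
    if config.method == "mbl":
        return timescale_mbl(binary, tip_ages, config.min_branch)
    return timescale_cal3(binary, occ, config.cal3_rates, s_date, tip_ages)


def make_ensemble(topology: Tree, occ: pd.DataFrame,
                  config: CalibrationConfig) -> list[Tree]:
    """Independent ensemble of dated trees (resolution x age draw x dating)."""
    validate_occurrences(occ)
    return [make_one(topology, occ, config, i) for i in range(config.n_trees)]
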