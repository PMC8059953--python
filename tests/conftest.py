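"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from morphodyn import make_world
from morphodyn.phylo import Tree
from morphodyn.simulate import default_mean_shape, random_deformation_basis


@pytest.fixture(scope="session")
def small_world():
    """24-tip homogeneous world shared by read-only tests."""
    return make_world(n_tips=24, seed=7)


@pytest.fixture(scope="session")
def shifted_world():
    """32-tip world with one clade planted at scalar 10."""
    return make_world(n_tips=32, shift_scalar=10.0, seed=13)


@pytest.fixture()
def cherry():
    tree = Tree.from_newick("(A:1,B:3);")
    tree.update_ages_from_lengths(tip_ages={"A": 2.0, "B": 0.0})
    return tree


@pytest.fixture(scope="session")
def shape_fixture():
    """Mean shape + 2-trait deformation basis for morphometric tests."""
    mean = default_mean_shape(12)
    basis = random_deformation_basis(mean, 2, seed=1)
    return mean, basis


def random_dated_tree(n_tips: int, seed: int) -> Tree:
    from morphodyn import simulate_phylogeny
    return simulate_phylogeny(n_tips, 0.25, 0.1, seed=seed)


def traits_frame(tip_traits: dict) -> pd.DataFrame:
    frame = pd.DataFrame({k: np.atleast_1d(v) for k, v in tip_traits.items()}).T
    frame.columns = [f"T{j + 1}" for j in range(frame.shape[1])]
    return frame
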