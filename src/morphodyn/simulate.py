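"""Synthetic worlds with known ground truth.

Everything the downstream analysis consumes — a dated phylogeny with extinct
tips, clade-structured rate regimes, multivariate Brownian traits, landmark
configurations built from those traits, and fossil occurrence ranges — is
generated here with a known answer, so that morphospace construction, tree
dating, disparity and rate inference can all be checked against truth.

Defaults emulate a fossil-dominated clade: a birth-death tree conditioned on
a total tip count (extinct tips retained), net diversification 0.03 per Myr
with substantial extinction, Brownian trait variance of 1e-3 per Myr (giving
morphospace-scale scores over a ~10^2 Myr tree), and first-appearance range
extensions of up to 5 Myr, comparable to stage-level dating uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, write_tps
from .phylo import Node, Tree


class SimulationExtinct(RuntimeError):
    """Raised when the birth-death process keeps dying before reaching size."""


# ----------------------------------------------------------------------
# tree simulation
# ----------------------------------------------------------------------
def simulate_phylogeny(n_tips: int, birth: float, death: float, seed: int,
                       max_tries: int = 1000) -> Tree:
    """Forward birth-death simulation conditioned on total tip count.

    The process runs until the total number of tips (extinct + extant)
    reaches ``n_tips``; the present is then set one further waiting time
    later so every pendant branch has positive duration.  Extant tips sit at
    age 0 Ma, extinct tips at their extinction ages.  The returned root is
    the first branching event (the initial stem is discarded).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth <= 0 or death < 0:
        raise ValueError("birth must be > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        tree = _try_simulate(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise SimulationExtinct(
        f"birth-death simulation went extinct {max_tries} times before "
        f"reaching {n_tips} tips (birth={birth}, death={death})")


def _try_simulate(n_tips, birth, death, rng):
    t = 0.0
    root = Node()
    birth_time: dict[int, float] = {id(root): 0.0}
    death_time: dict[int, float] = {}
    alive: list[Node] = [root]
    dead: list[Node] = []
    first = True
    while True:
        n_alive = len(alive)
        if n_alive == 0:
            return None
        total_rate = n_alive * (birth + death)
        t += rng.exponential(1.0 / total_rate)
        if not first and len(alive) + len(dead) >= n_tips:
            break  # present = time of the would-be next event
        pick = int(rng.integers(n_alive))
        lineage = alive[pick]
        if first or rng.random() < birth / (birth + death):
            first = False
            alive.pop(pick)
            for _ in range(2):
                child = Node()
                lineage.add_child(child)
                birth_time[id(child)] = t
                alive.append(child)
        else:
            alive.pop(pick)
            dead.append(lineage)
            death_time[id(lineage)] = t

    present = t
    tip_no = 0

    def finalize(node: Node) -> None:
        nonlocal tip_no
        if node.children:
            # an internal node's divergence time is its children's birth time
            node.age = present - birth_time[id(node.children[0])]
            for child in node.children:
                finalize(child)
        else:
            tip_no += 1
            node.label = f"t{tip_no}"
            if id(node) in death_time:  # extinct tip
                node.age = present - death_time[id(node)]
            else:                        # extant tip
                node.age = 0.0

    finalize(root)
    tree = Tree(root)
    tree.update_lengths_from_ages()
    try:
        tree.validate_dated(tol=0.0)
    except ValueError:
        return None
    return tree


# ----------------------------------------------------------------------
# rate regimes
# ----------------------------------------------------------------------
def assign_regimes(tree: Tree, shifts: list[tuple[Node | str, float]]) -> dict[Node, float]:
    """Per-branch rate scalars from clade-level shifts.

    Each shift ``(node, scalar)`` multiplies the scalar of every branch in
    the clade rooted at ``node``, the stem branch included.  Nested shifts
    compose multiplicatively; unaffected branches carry 1.
    """
    nodes = [n for n in tree.postorder() if n.parent is not None]
    regime: dict[Node, float] = {n: 1.0 for n in nodes}
    seen: set[int] = set()
    for loc, scalar in shifts:
        if scalar <= 0:
            raise ValueError(f"rate scalar must be > 0, got {scalar}")
        node = tree.find(loc) if isinstance(loc, str) else loc
        if id(node) in seen:
            raise ValueError(f"duplicate shift node {node!r}")
        seen.add(id(node))
        for member in tree.subtree_nodes(node):
            if member.parent is not None:
                regime[member] *= scalar
    return regime


# ----------------------------------------------------------------------
# trait evolution
# ----------------------------------------------------------------------
def simulate_bm_traits(tree: Tree, regime: dict[Node, float],
                       base_rates: np.ndarray, root_state: np.ndarray,
                       seed: int) -> tuple[dict[str, np.ndarray], dict[Node, np.ndarray]]:
    """Brownian trait evolution along a dated tree.

    Along a branch of duration t with scalar r, trait j receives an
    independent Normal(0, base_rates[j] * r * t) increment.  Returns
    (tip traits keyed by label, node traits keyed by node); the root carries
    ``root_state`` exactly.
    """
    base_rates = np.asarray(base_rates, dtype=float)
    root_state = np.asarray(root_state, dtype=float)
    rng = np.random.default_rng(seed)
    node_traits: dict[Node, np.ndarray] = {tree.root: root_state.copy()}
    tip_traits: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            value = node_traits[tree.root]
        else:
            t = node.parent.age - node.age
            if t <= 0:
                raise ValueError("all branch durations must be > 0")
            scale = np.sqrt(base_rates * regime.get(node, 1.0) * t)
            value = node_traits[node.parent] + rng.normal(0.0, 1.0, base_rates.size) * scale
            node_traits[node] = value
        if node.is_leaf():
            tip_traits[node.label] = value
    return tip_traits, node_traits


# ----------------------------------------------------------------------
# landmark construction
# ----------------------------------------------------------------------
def default_mean_shape(k: int = 20) -> np.ndarray:
    """A centred, unit-centroid-size reference shape (points on a circle)."""
    theta = 2 * np.pi * np.arange(k) / k
    shape = np.column_stack([np.cos(theta), np.sin(theta)])
    shape -= shape.mean(axis=0)
    return shape / np.sqrt((shape ** 2).sum())


def similarity_basis(mean_shape: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k x 4) of the similarity-transform subspace at a
    centred unit-size shape: two translations, scaling, and rotation."""
    k = mean_shape.shape[0]
    t1 = np.zeros((k, 2)); t1[:, 0] = 1.0
    t2 = np.zeros((k, 2)); t2[:, 1] = 1.0
    scale = mean_shape.copy()
    rot = np.column_stack([-mean_shape[:, 1], mean_shape[:, 0]])
    basis = np.column_stack([v.reshape(-1) for v in (t1, t2, scale, rot)])
    q, _ = np.linalg.qr(basis)
    return q


def random_deformation_basis(mean_shape: np.ndarray, n_traits: int, seed: int) -> np.ndarray:
    """Orthonormal deformation fields (2k x n) orthogonal to the similarity
    subspace of ``mean_shape``, so that trait scores act isometrically in
    Kendall tangent space."""
    k2 = 2 * mean_shape.shape[0]
    if n_traits > k2 - 4:
        raise ValueError("too many traits for this landmark count")
    rng = np.random.default_rng(seed)
    sim = similarity_basis(mean_shape)
    raw = rng.normal(size=(k2, n_traits))
    q, _ = np.linalg.qr(np.column_stack([sim, raw]))
    return q[:, 4:4 + n_traits]


def traits_to_landmarks(scores: dict[str, np.ndarray], mean_shape: np.ndarray,
                        basis: np.ndarray, nuisance_seed: int,
                        identity_nuisance: bool = False) -> dict[str, LandmarkConfiguration]:
    """Map trait vectors to landmark configurations.

    Each configuration is ``mean_shape + sum_j score_j * basis_j`` followed by
    a random rotation, translation, and log-uniform [0.5, 2] scaling — the
    nuisance transforms GPA must remove.  The basis must be orthonormal and
    orthogonal to the similarity subspace (checked to 1e-8).
    """
    basis = np.asarray(basis, dtype=float)
    gram = basis.T @ basis
    if not np.allclose(gram, np.eye(basis.shape[1]), atol=1e-8):
        raise ValueError("deformation basis is not orthonormal")
    sim = similarity_basis(mean_shape)
    if np.abs(sim.T @ basis).max() > 1e-8:
        raise ValueError("deformation basis not orthogonal to similarity subspace")
    rng = np.random.default_rng(nuisance_seed)
    k = mean_shape.shape[0]
    out: dict[str, LandmarkConfiguration] = {}
    for taxon in sorted(scores):
        s = np.atleast_1d(np.asarray(scores[taxon], dtype=float))
        coords = (mean_shape.reshape(-1) + basis @ s).reshape(k, 2)
        if not identity_nuisance:
            theta = rng.uniform(0.0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            scale = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
            shift = rng.normal(0.0, 1.0, size=2)
            coords = scale * coords @ rot.T + shift
        out[taxon] = LandmarkConfiguration(taxon=taxon, coords=coords)
    return out


# ----------------------------------------------------------------------
# occurrences
# ----------------------------------------------------------------------
def derive_occurrences(tree: Tree, max_range_extension: float, seed: int) -> pd.DataFrame:
    """FAD/LAD ranges bracketing the true tip ages.

    LAD equals the true tip age; FAD extends it by Uniform(0, min(extension,
    pendant branch duration)), so the range never reaches past the tip's
    origination.
    """
    if max_range_extension < 0:
        raise ValueError("max_range_extension must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in tree.leaves():
        duration = leaf.parent.age - leaf.age
        u = rng.uniform(0.0, min(max_range_extension, duration))
        rows.append({"taxon": leaf.label, "fad": leaf.age + u, "lad": leaf.age})
    return pd.DataFrame(rows, columns=["taxon", "fad", "lad"])


# ----------------------------------------------------------------------
# whole worlds
# ----------------------------------------------------------------------
@dataclass
class SimulatedWorld:
    """A complete synthetic dataset with ground truth."""

    tree: Tree
    regime: dict[Node, float]
    base_rates: np.ndarray
    tip_traits: dict[str, np.ndarray]
    node_traits: dict[Node, np.ndarray]
    occurrences: pd.DataFrame
    landmark_sets: dict[str, LandmarkConfiguration]
    mean_shape: np.ndarray
    basis: np.ndarray
    true_scores: dict[str, np.ndarray] = field(default_factory=dict)
    shift_nodes: list[tuple[Node, float]] = field(default_factory=list)
    seed: int = 0


def choose_clade(tree: Tree, min_frac: float, max_frac: float, seed: int) -> Node:
    """A random internal (non-root) node whose clade holds a tip fraction in
    [min_frac, max_frac]."""
    n = tree.n_leaves
    candidates = [node for node in tree.internal_nodes()
                  if node.parent is not None
                  and min_frac <= len(tree.clade_leaf_labels(node)) / n <= max_frac]
    if not candidates:
        raise ValueError("no clade in the requested size range")
    rng = np.random.default_rng(seed)
    return candidates[rng.integers(len(candidates))]


def make_world(n_tips: int = 64, birth: float = 0.07, death: float = 0.04,
               n_traits: int = 3, base_rate: float = 1e-3,
               shift_scalar: float | None = None,
               shift_clade_frac: tuple[float, float] = (0.2, 0.4),
               deformation_scale: float = 1.0,
               max_range_extension: float = 5.0,
               n_landmarks: int = 20, seed: int = 0) -> SimulatedWorld:
    """Build a full synthetic world.

    With ``shift_scalar`` set, one clade covering 20-40% of the tips is
    planted with that rate scalar (the recovery target for the rates module);
    otherwise evolution is homogeneous.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    tree = simulate_phylogeny(n_tips, birth, death, seeds[0])
    shifts: list[tuple[Node, float]] = []
    if shift_scalar is not None:
        node = choose_clade(tree, *shift_clade_frac, seed=seeds[1])
        shifts.append((node, shift_scalar))
    regime = assign_regimes(tree, shifts)
    base_rates = np.full(n_traits, base_rate)
    root_state = np.zeros(n_traits)
    tip_traits, node_traits = simulate_bm_traits(tree, regime, base_rates,
                                                 root_state, seeds[2])
    mean_shape = default_mean_shape(n_landmarks)
    basis = random_deformation_basis(mean_shape, n_traits, seeds[3])
    true_scores = {t: v * deformation_scale for t, v in tip_traits.items()}
    landmark_sets = traits_to_landmarks(true_scores, mean_shape, basis, seeds[4])
    occurrences = derive_occurrences(tree, max_range_extension, seeds[4])
    return SimulatedWorld(tree=tree, regime=regime, base_rates=base_rates,
                          tip_traits=tip_traits, node_traits=node_traits,
                          occurrences=occurrences, landmark_sets=landmark_sets,
                          mean_shape=mean_shape, basis=basis,
                          true_scores=true_scores, shift_nodes=shifts, seed=seed)


def write_world(world: SimulatedWorld, outdir) -> None:
    """Write the fixture files: landmarks.tps, tree.nwk, occurrences.csv,
    truth.json (regimes keyed by clade tip sets, base rates, true scores)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tps([world.landmark_sets[t] for t in sorted(world.landmark_sets)],
              out / "landmarks.tps")
    world.tree.write(out / "tree.nwk")
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    truth = {
        "seed": world.seed,
        "base_rates": [float(r) for r in world.base_rates],
        "shifts": [
            {"clade_tips": sorted(world.tree.clade_leaf_labels(node)),
             "scalar": float(scalar)}
            for node, scalar in world.shift_nodes
        ],
        "true_scores": {t: [float(x) for x in v]
                        for t, v in sorted(world.true_scores.items())},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
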