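"""Independent oracle implementations used by the test suite.

Each oracle computes the same quantity as the library by a different route
(dense matrices, exhaustive enumeration, double loops) and is kept free of
the implementation paths it checks.
"""

import heapq
import itertools

import numpy as np
from scipy.stats import multivariate_normal

from morphodyn import simulate_bm_traits, simulate_phylogeny
from morphodyn.rates import LikelihoodEngine


def mpd_oracle(points):
    n = len(points)
    total = sum(np.linalg.norm(points[i] - points[j])
                for i in range(n) for j in range(i + 1, n))
    return total / (n * (n - 1) / 2)


def mst_oracle(points):
    """Exhaustive minimum over all labeled spanning trees via Pruefer
    sequences; n <= 7."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    if n == 2:
        return float(d[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        deg = [1] * n
        for v in seq:
            deg[v] += 1
        total = 0.0
        heap = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(heap)
        for v in seq:
            leaf = heapq.heappop(heap)
            total += d[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u = heapq.heappop(heap)
        w = heapq.heappop(heap)
        best = min(best, total + d[u, w])
    return float(best)


def dense_loglik(tree, traits, sigma2, scalars_by_node, root_states):
    """Explicit multivariate-normal evaluation with the scaled shared-path
    covariance matrix."""
    labels = list(traits.index)
    scaled_depth = {}
    for node in tree.preorder():
        if node.parent is None:
            scaled_depth[id(node)] = 0.0
        else:
            t = node.parent.age - node.age
            scaled_depth[id(node)] = (scaled_depth[id(node.parent)]
                                      + t * scalars_by_node.get(id(node), 1.0))

    def path(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    tipmap = {leaf.label: leaf for leaf in tree.leaves()}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                C[i, j] = scaled_depth[id(tipmap[a])]
            else:
                anc_a = {id(x) for x in path(tipmap[a])}
                mrca = next(x for x in path(tipmap[b]) if id(x) in anc_a)
                C[i, j] = scaled_depth[id(mrca)]
    ll = 0.0
    for k in range(traits.shape[1]):
        x = traits.loc[labels].iloc[:, k].to_numpy()
        ll += multivariate_normal(mean=np.full(n, root_states[k]),
                                  cov=sigma2[k] * C).logpdf(x)
    return float(ll)


def random_bm_instance(seed, traits_frame, n_tips=None, p=None):
    """A random dated tree + traits + shift configuration for oracle checks."""
    rng = np.random.default_rng(seed)
    n_tips = n_tips or int(rng.integers(4, 13))
    p = p or int(rng.integers(1, 5))
    tree = simulate_phylogeny(n_tips, 0.3, 0.1, seed=seed)
    regime = {n: 1.0 for n in tree.postorder() if n.parent is not None}
    tips, _ = simulate_bm_traits(tree, regime, np.ones(p), np.zeros(p),
                                 seed=seed + 1)
    traits = traits_frame(tips)
    engine = LikelihoodEngine(tree, traits)
    nodes = tree.reindex()
    shifts = {}
    for _ in range(int(rng.integers(0, 4))):
        kind = "branch" if rng.random() < 0.5 else "clade"
        locs = engine.branch_locs if kind == "branch" else engine.clade_locs
        if not locs:
            continue
        idx = int(locs[rng.integers(len(locs))])
        shifts.setdefault((kind, idx), float(np.exp(rng.normal(0, 1))))
    scal = engine.branch_scalars(shifts)
    by_node = {id(n): scal[n.index] for n in nodes if n.parent is not None}
    sigma2 = np.exp(rng.normal(0, 0.5, p))
    roots = rng.normal(0, 1, p)
    return tree, traits, sigma2, shifts, by_node, roots
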