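"""Disparity metrics, binning, bootstrap machinery, and phylogenetic
time-slicing with Brownian ancestral state estimation.

Metrics
-------
* ``mean_pairwise_distance`` — average dissimilarity (Procrustes distance for
  aligned shapes, Euclidean for morphospace scores);
* ``mst_length`` — total Euclidean minimum spanning tree length, a measure of
  the spread of morphospace occupation;
* ``alpha_shape_volume`` — 3D alpha-shape volume of the first three
  morphospace axes, a measure of expanse robust to outliers;
* ``partial_disparity`` — Foote's additive group contributions to total
  variance-style disparity.

Sparse samples (n < 2, or n < 4 for volumes) yield NaN, never zero: an empty
time bin is missing data, not an absence of disparity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .phylo import Node, Tree

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# point metrics
# ----------------------------------------------------------------------
def mean_pairwise_distance(points: np.ndarray) -> float:
    """Mean of all unordered pairwise Euclidean distances; NaN if n < 2."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        return float("nan")
    return float(pdist(points).mean())


def mst_length(points: np.ndarray) -> float:
    """Total edge length of the Euclidean minimum spanning tree; NaN if n < 2.

    Duplicate points are legal (zero-length edges)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        return float("nan")
    dist = squareform(pdist(points))
    # csgraph treats 0 as "no edge"; offset so duplicate points keep an edge
    tree = minimum_spanning_tree(csr_matrix(dist + 1.0))
    return float(tree.sum() - (n - 1))


def _circumradius(tetra: np.ndarray) -> float:
    """Circumradius of a tetrahedron given its 4x3 vertex array."""
    a = tetra[1:] - tetra[0]
    b = (tetra[1:] ** 2 - tetra[0] ** 2).sum(axis=1) / 2.0
    try:
        center = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return float("inf")
    return float(np.linalg.norm(center - tetra[0]))


def alpha_shape_volume(points: np.ndarray, alpha: float = np.inf) -> float:
    """Alpha-shape volume of a 3D point cloud.

    The Delaunay tetrahedralisation is computed and tetrahedra with
    circumradius <= ``alpha`` are retained; their summed volume is returned.
    ``alpha = inf`` gives the convex-hull volume.  Degenerate (coplanar)
    input yields volume 0 with a logged warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("alpha_shape_volume expects points in 3 dimensions")
    if points.shape[0] < 4:
        return float("nan")
    if np.isinf(alpha):
        try:
            return float(ConvexHull(points).volume)
        except QhullError:
            logger.warning("degenerate (coplanar) point set: volume 0")
            return 0.0
    try:
        tri = Delaunay(points)
    except QhullError:
        logger.warning("degenerate (coplanar) point set: volume 0")
        return 0.0
    total = 0.0
    for simplex in tri.simplices:
        verts = points[simplex]
        if _circumradius(verts) <= alpha:
            total += abs(np.linalg.det(verts[1:] - verts[0])) / 6.0
    return float(total)


def partial_disparity(scores: dict[str, np.ndarray],
                      groups: dict[str, str]) -> dict[str, float]:
    """Foote partial disparities: PD_g = sum_{i in g} ||x_i - centroid||^2 / (N-1).

    Group contributions sum exactly to the total variance-style disparity.
    Every taxon must carry a group label; an absent group contributes 0.
    """
    taxa = sorted(scores)
    missing = [t for t in taxa if t not in groups]
    if missing:
        raise ValueError(f"taxa without group labels: {missing}")
    x = np.array([np.atleast_1d(scores[t]) for t in taxa], dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("partial disparity needs >= 2 taxa")
    dev = ((x - x.mean(axis=0)) ** 2).sum(axis=1) / (n - 1)
    out: dict[str, float] = {}
    for taxon, d in zip(taxa, dev):
        out[groups[taxon]] = out.get(groups[taxon], 0.0) + float(d)
    return out


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------
def rarefy_metric(points: np.ndarray, target_n: int, metric, n_draws: int,
                  seed: int) -> float:
    """Partial rarefaction: subsample only when n exceeds the target.

    Bins larger than ``target_n`` are reduced to it (mean metric over
    ``n_draws`` subsamples without replacement); smaller bins keep their
    original sample.
    """
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n <= target_n:
        return float(metric(points))
    rng = np.random.default_rng(seed)
    vals = [metric(points[rng.choice(n, size=target_n, replace=False)])
            for _ in range(n_draws)]
    return float(np.mean(vals))


def bootstrap_ci(points: np.ndarray, metric, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval of a metric (resampling with replacement)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    vals = np.array([metric(points[rng.integers(0, n, size=n)])
                     for _ in range(n_boot)])
    lo, hi = np.nanpercentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# time bins
# ----------------------------------------------------------------------
@dataclass
class TimeBins:
    """Ordered, non-overlapping [older, younger) intervals in Ma."""

    table: pd.DataFrame  # columns: label, older, younger

    def __post_init__(self):
        required = {"label", "older", "younger"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"bins table needs columns {sorted(required)}")
        t = self.table.sort_values("older", ascending=False).reset_index(drop=True)
        if not (t["older"] > t["younger"]).all():
            raise ValueError("each bin needs older > younger")
        overlap = t["younger"].values[:-1] < t["older"].values[1:]
        if overlap.any():
            raise ValueError("bins overlap")
        self.table = t

    @classmethod
    def from_csv(cls, path) -> "TimeBins":
        return cls(pd.read_csv(path))

    @classmethod
    def uniform(cls, oldest: float, youngest: float, n: int) -> "TimeBins":
        edges = np.linspace(oldest, youngest, n + 1)
        rows = [{"label": f"bin{i + 1}", "older": edges[i], "younger": edges[i + 1]}
                for i in range(n)]
        return cls(pd.DataFrame(rows))

    def __iter__(self):
        return iter(self.table.itertuples(index=False))

    def midpoints(self) -> np.ndarray:
        return ((self.table["older"] + self.table["younger"]) / 2).to_numpy()


def bin_membership(occ: pd.DataFrame, bins: TimeBins) -> dict[str, set]:
    """Assign taxa to every bin their [FAD, LAD] range overlaps.

    Bins are closed on the older bound and open on the younger bound, so a
    point range sitting exactly on a boundary falls in the bin whose older
    edge it touches.  Taxa outside all bins are logged and excluded.
    """
    membership: dict[str, set] = {b.label: set() for b in bins}
    for row in occ.itertuples(index=False):
        hit = False
        for b in bins:
            if row.fad > b.younger and row.lad <= b.older:
                membership[b.label].add(row.taxon)
                hit = True
        if not hit:
            logger.warning("taxon %s (%.3g-%.3g Ma) outside all bins; excluded",
                           row.taxon, row.fad, row.lad)
    return membership


# ----------------------------------------------------------------------
# ancestral states & time slicing
# ----------------------------------------------------------------------
def ancestral_states(tree: Tree, tip_traits: dict[str, np.ndarray]) -> dict[Node, np.ndarray]:
    """Maximum-likelihood Brownian ancestral states at every internal node.

    The joint ML (equivalently, posterior-mean) states minimise
    sum over branches of (delta trait)^2 / duration with the tips held fixed,
    a sparse weighted-Laplacian linear system solved exactly per trait.
    """
    nodes = tree.reindex()
    leaves = [n for n in nodes if n.is_leaf()]
    missing = [n.label for n in leaves if n.label not in tip_traits]
    if missing:
        raise ValueError(f"missing tip traits for: {sorted(missing)}")
    p = np.atleast_1d(np.asarray(tip_traits[leaves[0].label], dtype=float)).size
    internals = [n for n in nodes if not n.is_leaf()]
    pos = {id(n): i for i, n in enumerate(internals)}
    ni = len(internals)
    rows, cols, vals = [], [], []
    b = np.zeros((ni, p))
    diag = np.zeros(ni)
    for node in nodes:
        if node.parent is None:
            continue
        w = 1.0 / (node.parent.age - node.age)
        i = pos[id(node.parent)]
        diag[i] += w
        if node.is_leaf():
            b[i] += w * np.atleast_1d(np.asarray(tip_traits[node.label], float))
        else:
            j = pos[id(node)]
            diag[j] += w
            rows += [i, j]
            cols += [j, i]
            vals += [-w, -w]
    rows += list(range(ni))
    cols += list(range(ni))
    vals += list(diag)
    A = csr_matrix((vals, (rows, cols)), shape=(ni, ni))
    sol = spsolve(A, b)
    sol = np.atleast_2d(sol)
    if sol.shape != (ni, p):
        sol = sol.reshape(ni, p)
    return {node: sol[pos[id(node)]] for node in internals}


def lineage_values_at(tree: Tree, tip_traits: dict[str, np.ndarray],
                      node_traits: dict[Node, np.ndarray], t: float,
                      model: str = "gradual") -> np.ndarray:
    """Trait values of every lineage crossing age ``t`` (Ma).

    ``gradual`` interpolates linearly along each crossing branch (the
    Brownian expectation conditional on the endpoints);
    ``punctuated-parent`` / ``punctuated-child`` take the older / younger
    endpoint value.  A tip or node exactly at ``t`` contributes its own value.
    """
    if model not in ("gradual", "punctuated-parent", "punctuated-child"):
        raise ValueError(f"unknown time-slice model {model!r}")
    if t > tree.root.age:
        raise ValueError(f"slice time {t} Ma is older than the root "
                         f"({tree.root.age} Ma)")

    def value_of(node: Node) -> np.ndarray:
        if node.is_leaf():
            return np.atleast_1d(np.asarray(tip_traits[node.label], float))
        return np.atleast_1d(np.asarray(node_traits[node], float))

    out: list[np.ndarray] = []
    for node in tree.postorder():
        if node.parent is None:
            if node.age == t:
                out.append(value_of(node))
            continue
        older, younger = node.parent.age, node.age
        if younger == t:
            out.append(value_of(node))
        elif older > t > younger:
            if model == "punctuated-parent":
                out.append(value_of(node.parent))
            elif model == "punctuated-child":
                out.append(value_of(node))
            else:
                frac = (older - t) / (older - younger)
                out.append(value_of(node.parent) +
                           frac * (value_of(node) - value_of(node.parent)))
    return np.array(out) if out else np.empty((0, 1))


# ----------------------------------------------------------------------
# series assembly
# ----------------------------------------------------------------------
METRICS = {
    "mpd": mean_pairwise_distance,
    "mst": mst_length,
}


def resolve_metric(metric, alpha: float = np.inf):
    if callable(metric):
        return metric
    if metric in METRICS:
        return METRICS[metric]
    if metric == "alpha":
        return lambda pts: alpha_shape_volume(np.atleast_2d(pts)[:, :3], alpha)
    raise ValueError(f"unknown metric {metric!r}")


def binned_disparity(scores: dict[str, np.ndarray], occ: pd.DataFrame,
                     bins: TimeBins, metric="mpd", alpha: float = np.inf,
                     n_boot: int = 1000, rarefy: bool = False,
                     n_draws: int = 200, seed: int = 0) -> pd.DataFrame:
    """Within-bin disparity with bootstrap CIs and optional partial rarefaction.

    The rarefaction target is the mean within-bin sample size rounded to the
    nearest integer; bins below the target keep their full sample.
    """
    fn = resolve_metric(metric, alpha)
    membership = bin_membership(occ, bins)
    sizes = [len(membership[b.label]) for b in bins]
    target = max(2, int(round(np.mean([s for s in sizes if s > 0])))) if any(sizes) else 2
    ss = np.random.SeedSequence(seed)
    rows = []
    for b, child in zip(bins, ss.spawn(len(sizes))):
        taxa = sorted(membership[b.label])
        sub_seeds = child.generate_state(2) % (2 ** 31)
        if len(taxa) < 2:
            rows.append({"label": b.label, "older": b.older, "younger": b.younger,
                         "value": np.nan, "lower": np.nan, "upper": np.nan,
                         "n": len(taxa)})
            continue
        pts = np.array([np.atleast_1d(scores[t]) for t in taxa])
        if rarefy:
            value = rarefy_metric(pts, target, fn, n_draws, int(sub_seeds[0]))
        else:
            value = float(fn(pts))
        lo, hi = bootstrap_ci(pts, fn, n_boot=n_boot, seed=int(sub_seeds[1]))
        rows.append({"label": b.label, "older": b.older, "younger": b.younger,
                     "value": value, "lower": lo, "upper": hi, "n": len(taxa)})
    return pd.DataFrame(rows)


def disparity_through_time(ensemble: list[Tree], tip_traits: dict[str, np.ndarray],
                           slice_times: np.ndarray, metric="mpd",
                           model: str = "gradual",
                           alpha: float = np.inf) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phylogenetically time-sliced disparity over a tree ensemble.

    For every tree, ancestral states are estimated and the metric is applied
    to the lineage values crossing each slice time ("spaghetti" series).
    Returns (per-tree long table, across-tree summary with median and a 95%
    envelope).  Slices with < 2 lineages are NaN.
    """
    fn = resolve_metric(metric, alpha)
    slice_times = np.asarray(slice_times, dtype=float)
    rows = []
    for idx, tree in enumerate(ensemble):
        anc = ancestral_states(tree, tip_traits)
        for t in slice_times:
            if t > tree.root.age:
                value, n = np.nan, 0
            else:
                pts = lineage_values_at(tree, tip_traits, anc, t, model)
                n = pts.shape[0]
                value = float(fn(pts)) if n >= 2 else np.nan
            rows.append({"tree_index": idx, "time": t, "value": value, "n": n})
    series = pd.DataFrame(rows)
    summary = (series.groupby("time")["value"]
               .agg(median="median",
                    lower=lambda v: np.nanquantile(v, 0.025) if v.notna().any() else np.nan,
                    upper=lambda v: np.nanquantile(v, 0.975) if v.notna().any() else np.nan)
               .reset_index())
    return series, summary
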