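"""End-to-end orchestration: align -> ordinate -> date -> disparity -> rates.

A single :class:`PipelineConfig` (YAML/JSON-friendly) drives the full
analysis on either user-supplied files (TPS landmarks, Newick topology,
occurrence and bin CSVs) or a freshly simulated synthetic world.  Every
stage derives its own random substream from the global seed, all artifacts
are written as text (CSV / Newick / JSON), and a manifest with seeds and
SHA-256 checksums makes reruns verifiable: identical config + seed gives a
bit-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disparity as D
from . import rates as R
from . import simulate as S
from . import timescale as TS
from .landmarks import SlidingSpec, read_tps
from .ordination import broken_stick, principal_components
from .phylo import Tree
from .procrustes import generalized_procrustes

logger = logging.getLogger("morphodyn.pipeline")

_VALID_METRICS = ("mpd", "mst", "alpha")


@dataclass
class PipelineConfig:
    """Everything needed for one full run.

    Either point ``landmarks/tree/occurrences`` at files, or set
    ``simulate`` parameters (then inputs are generated and written first).
    """

    out_dir: str = "morphodyn_out"
    seed: int = 0
    # inputs ------------------------------------------------------------
    landmarks: str | None = None           # TPS path
    tree: str | None = None                # Newick path
    occurrences: str | None = None         # CSV path
    bins: str | None = None                # CSV path; default: uniform bins
    sliding_curves: list[list[int]] = field(default_factory=list)
    simulate: dict | None = None           # kwargs for simulate.make_world
    # morphometrics ------------------------------------------------------
    n_axes: int | None = None              # None -> broken stick (min 1)
    # dating -------------------------------------------------------------
    dating_method: str = "mbl"
    min_branch: float = 1.0
    root_extension: float = 10.0
    cal3_rates: tuple = (0.1, 0.1, 0.5)
    n_trees: int = 100
    # disparity ----------------------------------------------------------
    metrics: tuple = ("mpd", "mst")
    alpha_list: tuple = (float("inf"),)
    n_boot: int = 1000
    rarefy: bool = True
    n_bins: int = 24
    n_slices: int = 24
    slice_model: str = "gradual"
    # rates --------------------------------------------------------------
    rates_trees: int = 5                   # subset of the ensemble
    chain: dict = field(default_factory=dict)  # ChainConfig overrides
    run_rates: bool = True
    run_marginal_likelihood: bool = True

    def validate(self) -> None:
        for m in self.metrics:
            if m not in _VALID_METRICS:
                raise ValueError(f"unknown disparity metric {m!r}; "
                                 f"choose from {_VALID_METRICS}")
        if self.dating_method not in ("equal", "mbl", "cal3"):
            raise ValueError(f"unknown dating method {self.dating_method!r}")
        if self.slice_model not in ("gradual", "punctuated-parent",
                                    "punctuated-child"):
            raise ValueError(f"unknown slice model {self.slice_model!r}")
        if self.simulate is None:
            for name in ("landmarks", "tree", "occurrences"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"either 'simulate' or '{name}' must be set")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _derive_seed(root_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stage order: simulate/load inputs -> GPA (+ sliding) -> PCA -> axis
    selection -> dated-tree ensemble -> within-bin disparity with bootstrap
    CIs -> partial disparity -> time-sliced disparity per tree -> variable
    rates on a configurable ensemble subset -> Bayes factor -> consensus
    scalar tree -> rates through time.  Any stage failure aborts with the
    stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}, "files": {}}
    stage = "init"
    t0 = time.time()
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        if config.simulate is not None:
            world = S.make_world(seed=_derive_seed(config.seed, 0),
                                 **config.simulate)
            S.write_world(world, out / "world")
            lm_path = out / "world" / "landmarks.tps"
            tree_path = out / "world" / "tree.nwk"
            occ_path = out / "world" / "occurrences.csv"
        else:
            lm_path, tree_path, occ_path = (Path(config.landmarks),
                                            Path(config.tree),
                                            Path(config.occurrences))
        configs = read_tps(lm_path)
        topology = Tree.from_newick(str(tree_path))
        occ = TS.read_occurrences(occ_path)
        manifest["stages"]["inputs"] = {"n_taxa": len(configs),
                                        "n_tips": topology.n_leaves}

        # ------------------------------------------------- align & ordinate
        stage = "align"
        sliding = SlidingSpec(curves=[list(c) for c in config.sliding_curves]) \
            if config.sliding_curves else None
        aligned = generalized_procrustes(configs, sliding=sliding)
        stage = "ordinate"
        ordination = principal_components(aligned)
        n_axes = config.n_axes or max(1, broken_stick(ordination.eigenvalues))
        scores_frame = ordination.scores_frame()
        _write_csv(scores_frame.reset_index(names="taxon"), out / "scores.csv")
        _write_csv(pd.DataFrame({"eigenvalue": ordination.eigenvalues,
                                 "var_prop": ordination.var_prop}),
                   out / "eigenvalues.csv")
        manifest["stages"]["ordinate"] = {
            "n_axes_used": int(n_axes),
            "broken_stick": int(broken_stick(ordination.eigenvalues)),
            "var_prop_leading": [round(float(v), 6)
                                 for v in ordination.var_prop[:4]],
        }
        scores = {t: ordination.scores[i, :n_axes]
                  for i, t in enumerate(ordination.taxa)}

        # ------------------------------------------------------------ dating
        stage = "timescale"
        cal = TS.CalibrationConfig(method=config.dating_method,
                                   min_branch=config.min_branch,
                                   root_extension=config.root_extension,
                                   cal3_rates=tuple(config.cal3_rates),
                                   n_trees=config.n_trees,
                                   seed=_derive_seed(config.seed, 1))
        ensemble = TS.make_ensemble(topology, occ, cal)
        with open(out / "ensemble.nwk", "w") as fh:
            for tree in ensemble:
                fh.write(tree.to_newick() + "\n")

        # --------------------------------------------------------- disparity
        stage = "disparity"
        oldest = float(occ["fad"].max())
        if config.bins:
            bins = D.TimeBins.from_csv(config.bins)
        else:
            bins = D.TimeBins.uniform(oldest, 0.0, config.n_bins)
        for mi, metric in enumerate(config.metrics):
            alphas = config.alpha_list if metric == "alpha" else (float("inf"),)
            frames = []
            for alpha in alphas:
                frame = D.binned_disparity(
                    scores, occ, bins, metric=metric, alpha=alpha,
                    n_boot=config.n_boot, rarefy=config.rarefy,
                    seed=_derive_seed(config.seed, 2, mi))
                frame.insert(0, "alpha", alpha)
                frames.append(frame)
            _write_csv(pd.concat(frames, ignore_index=True),
                       out / f"disparity_{metric}.csv")

        stage = "partial_disparity"
        groups = _partial_groups(config, topology, out)
        if groups is not None:
            pd_frame = pd.DataFrame(
                sorted(D.partial_disparity(scores, groups).items()),
                columns=["group", "partial_disparity"])
            _write_csv(pd_frame, out / "partial_disparity.csv")

        stage = "dtt"
        root_span = min(t.root.age for t in ensemble)
        slice_times = np.linspace(root_span * 0.999, 0.0, config.n_slices)
        for mi, metric in enumerate(config.metrics):
            series, summary = D.disparity_through_time(
                ensemble, scores, slice_times, metric=metric,
                model=config.slice_model,
                alpha=config.alpha_list[0])
            _write_csv(series, out / f"dtt_{metric}_series.csv")
            _write_csv(summary, out / f"dtt_{metric}_summary.csv")

        # ------------------------------------------------------------- rates
        if config.run_rates:
            stage = "rates"
            traits = scores_frame.iloc[:, :n_axes]
            posteriors = []
            bfs = []
            subset = ensemble[:min(config.rates_trees, len(ensemble))]
            for i, tree in enumerate(subset):
                chain = R.ChainConfig(seed=_derive_seed(config.seed, 3, i),
                                      **config.chain)
                post = R.rjmcmc_variable_rates(tree, traits, chain)
                posteriors.append(post)
                if config.run_marginal_likelihood:
                    ml_var = R.stepping_stone(tree, traits, "variable", chain)
                    ml_hom = R.stepping_stone(tree, traits, "homogeneous", chain)
                    bfs.append(R.bayes_factor(ml_var, ml_hom))
            posteriors[0].trace.to_csv(out / "rates_trace.csv", index=False,
                                       float_format="%.12g")
            consensus = R.mean_scalar_tree(posteriors)
            consensus.write(out / "consensus_rates.nwk")
            rtt = R.rates_through_time(posteriors, bin_width=max(1.0, oldest / 200))
            _write_csv(rtt, out / "rates_through_time.csv")
            manifest["stages"]["rates"] = {
                "n_trees": len(posteriors),
                "mean_n_shifts": float(np.mean(
                    [p.trace["n_shifts"].mean() for p in posteriors])),
                "bayes_factors": [round(b, 4) for b in bfs],
                "min_ess": float(min(min(p.ess.values()) for p in posteriors)),
            }

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["seed"] = config.seed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["metrics"] = list(d["metrics"])
    d["alpha_list"] = [("inf" if np.isinf(a) else a) for a in d["alpha_list"]]
    d["cal3_rates"] = list(d["cal3_rates"])
    return d


def _partial_groups(config: PipelineConfig, topology: Tree, out: Path):
    """Group labels for partial disparity.

    For simulated inputs the planted-shift clade (from truth.json) versus
    background is used; otherwise two clades split at the root.
    """
    tips = topology.leaf_labels()
    if config.simulate is not None:
        truth = json.loads((out / "world" / "truth.json").read_text())
        if truth["shifts"]:
            clade = set(truth["shifts"][0]["clade_tips"])
            return {t: ("shifted" if t in clade else "background") for t in tips}
    if len(topology.root.children) < 2:
        return None
    first = topology.clade_leaf_labels(topology.root.children[0])
    return {t: ("cladeA" if t in first else "cladeB") for t in tips}


def report(out_dir, show: bool = False) -> list:
    """Render summary figures from a completed run directory.

    Produces disparity-through-time spaghetti plots with envelopes, the
    consensus tree coloured by mean rate scalar, and rates-through-time
    curves.  Missing artifacts are skipped with a note; an empty bundle is
    an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    if not out.exists() or not any(out.iterdir()):
        raise FileNotFoundError(f"no pipeline outputs in {out}")
    made = []
    for metric_file in sorted(out.glob("dtt_*_series.csv")):
        metric = metric_file.stem.replace("dtt_", "").replace("_series", "")
        series = pd.read_csv(metric_file)
        summary = pd.read_csv(out / f"dtt_{metric}_summary.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        for _, grp in series.groupby("tree_index"):
            ax.plot(grp["time"], grp["value"], color="0.7", lw=0.5)
        ax.plot(summary["time"], summary["median"], color="k", lw=2)
        ax.fill_between(summary["time"], summary["lower"], summary["upper"],
                        alpha=0.25)
        ax.invert_xaxis()
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel(metric)
        fig.savefig(out / f"fig_dtt_{metric}.png", dpi=120)
        plt.close(fig)
        made.append(f"fig_dtt_{metric}.png")
    rtt_path = out / "rates_through_time.csv"
    if rtt_path.exists():
        rtt = pd.read_csv(rtt_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        mid = (rtt["bin_older"] + rtt["bin_younger"]) / 2
        ax.plot(mid, rtt["mean_rate"], color="k")
        ax.axhline(1.0, color="0.6", ls="--")
        ax.invert_xaxis()
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel("mean rate scalar")
        fig.savefig(out / "fig_rates_through_time.png", dpi=120)
        plt.close(fig)
        made.append("fig_rates_through_time.png")
    cons_path = out / "consensus_rates.nwk"
    if cons_path.exists():
        tree = Tree.from_newick(str(cons_path))
        fig, ax = plt.subplots(figsize=(6, 8))
        _plot_scalar_tree(tree, ax)
        fig.savefig(out / "fig_consensus_rates.png", dpi=120)
        plt.close(fig)
        made.append("fig_consensus_rates.png")
    if not made:
        raise FileNotFoundError(f"{out} holds no plottable artifacts")
    return made


def _plot_scalar_tree(tree: Tree, ax) -> None:
    """Minimal rectangular tree plot with branches coloured by scalar."""
    import matplotlib.cm as cm
    import matplotlib.colors as mcolors

    leaves = tree.leaves()
    ypos = {id(leaf): i for i, leaf in enumerate(leaves)}
    depth = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + 1.0
    for node in tree.postorder():
        if node.children:
            ypos[id(node)] = np.mean([ypos[id(c)] for c in node.children])
    scalars = [n.length for n in tree.postorder() if n.length is not None]
    norm = mcolors.LogNorm(vmin=max(min(scalars), 1e-3), vmax=max(max(scalars), 1.0))
    cmap = cm.coolwarm
    for node in tree.postorder():
        if node.parent is None:
            continue
        color = cmap(norm(max(node.length or 1.0, 1e-3)))
        y = ypos[id(node)]
        ax.plot([depth[id(node.parent)], depth[id(node)]], [y, y], color=color, lw=1.5)
        ax.plot([depth[id(node.parent)]] * 2,
                [ypos[id(node.parent)], y], color=color, lw=1.0)
    ax.set_yticks([])
    ax.set_xlabel("node depth")
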