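"""Disparity through time: within-bin metrics and phylogenetic time-slicing.

Measures mean pairwise distance in time bins from the occurrence records
(with bootstrap CIs), then re-measures disparity along a dated tree with
Brownian ancestral estimates filling the lineages a bin-based sample
misses.
"""

import numpy as np

from morphodyn import (TimeBins, binned_disparity, disparity_through_time,
                       make_world, partial_disparity)

world = make_world(n_tips=32, shift_scalar=10.0, seed=1)
scores = world.true_scores

bins = TimeBins.uniform(world.occurrences["fad"].max(), 0.0, 8)
table = binned_disparity(scores, world.occurrences, bins, metric="mpd",
                         n_boot=500, seed=0)
print("within-bin MPD (older -> younger):")
for row in table.itertuples(index=False):
    val = "   n/a" if np.isnan(row.value) else f"{row.value:6.3f}"
    print(f"  {row.older:6.1f}-{row.younger:6.1f} Ma  MPD {val}  (n={row.n})")

times = np.linspace(world.tree.root.age * 0.99, 0.0, 8)
_, summary = disparity_through_time([world.tree], world.tip_traits, times,
                                    metric="mpd")
print("\ntime-sliced MPD (ancestral lineages included):")
for row in summary.itertuples(index=False):
    print(f"  {row.time:6.1f} Ma  MPD {row.median:6.3f}")

node, _ = world.shift_nodes[0]
clade = world.tree.clade_leaf_labels(node)
groups = {t: ("shifted" if t in clade else "background") for t in scores}
print("\nFoote partial disparity (sums to the total):")
for group, value in sorted(partial_disparity(scores, groups).items()):
    print(f"  {group:>10}: {value:.4f}")
# The fast-evolving clade contributes disproportionately to total
# disparity, and time-sliced MPD is nonzero even in sparsely sampled
# intervals because ancestral lineages fill them.
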