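"""Local phylogeny of an admixed genome: per-variant trees and identity
tracks.

A mosaic strain descends from different founders on different chromosome
arms, so no single tree describes it; the local NJ tree changes along the
genome and a sliding-window identity track to one parent drops sharply at
the recorded crossover.
"""

import numpy as np

from remergence import (
    AdmixtureParams,
    GenomeModel,
    WindowSpec,
    build_admixed_population,
    identity_track,
    local_tree_for_variant,
)

genome = GenomeModel.yeast(0.05)
params = AdmixtureParams(muts_per_founder=2000, muts_per_strain_post=0)
pop = build_admixed_population(params, genome, rng=np.random.default_rng(11))
m = pop.matrix

tree = local_tree_for_variant(m, m.n_loci // 2, WindowSpec(200))
print("local midpoint-rooted NJ tree at the genome midpoint:")
print(tree.to_newick().strip()[:120], "...")

bp = pop.breakpoints
row = bp[(bp["mosaic"] == "M01") & (bp["chrom"] == "chrIV")].iloc[0]
parent = row["left_parent"]
print(f"\nM01 inherited the left arm of chrIV from {parent} "
      f"(crossover at {row['breakpoint']:,} bp)")

track = identity_track("M01", parent, m, WindowSpec(60), stride=20)
track = track[track["chrom"] == "chrIV"]
for _, r in track.iloc[::4].iterrows():
    side = "left " if r["center_pos"] <= row["breakpoint"] else "right"
    print(f"  {side} of crossover, pos {int(r['center_pos']):>8,}: "
          f"identity {r['identity']:.3f}")
# Identity near 1 left of the crossover (inherited haplotype) and lower
# to the right (the other parent's haplotype plus founder divergence).
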