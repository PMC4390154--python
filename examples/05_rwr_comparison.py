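"""Connectivity-significance detection vs random walk with restart.

Both rank candidate genes from the same seeds; the module detector recalls
more of the planted module early (high precision in the first picks), the
diffusion walk catches up over long horizons, and the walk's top picks are
biased toward hubs.
"""

import numpy as np

from diamonet import (
    RWRConfig, run_recovery, rwr_rank, rwr_scores, sample_module,
    synthetic_interactome,
)

net = synthetic_interactome(n_nodes=1200, mean_degree=10, rng_seed=42)
module = sample_module(net, "connectivity", target_size=40, rng_seed=1)


def walk_ranker(g, kept, n):
    return rwr_rank(rwr_scores(g, kept, RWRConfig(restart_r=0.4)), kept)[:n]


dia = run_recovery(net, module, 0.5, n_iterations=150, rng_seed=5)
walk = run_recovery(net, module, 0.5, n_iterations=150, rng_seed=5,
                    ranker=walk_ranker)

print("recall of the 20 removed module members (same seeds, same network):")
print("iter   detector   random walk")
for it in (5, 10, 20, 50, 150):
    print(f"{it:4d}   {dia.recall_at(it):8.2f}   {walk.recall_at(it):11.2f}")

# hub bias: mean degree of the first 20 picks of each method
from diamonet import DiamondConfig, SeedSet, run_diamond

seeds = SeedSet("kept", dia.kept_seeds)
dia_top = run_diamond(net, seeds, DiamondConfig(20)).genes
walk_top = walk_ranker(net, seeds, 20)
deg = net.graph.degree
print(f"\nmean degree of first 20 picks: detector "
      f"{np.mean([deg[g] for g in dia_top]):.1f}, walk "
      f"{np.mean([deg[g] for g in walk_top]):.1f}")
print("the walk favors hubs; connectivity significance discounts them")
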