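"""Localization statistics of a protein set: LCC significance and local
modularity R.

Disease proteins typically induce a largest connected component (LCC) far
larger than same-size random sets (high z-score) while forming a poorly
separated community (R near 0) — the observation motivating significance-
based, rather than density-based, module detection.
"""

from diamonet import (
    SeedSet, lcc_significance, local_modularity, sample_module,
    synthetic_interactome,
)

net = synthetic_interactome(n_nodes=1200, mean_degree=10, rng_seed=42)
module = sample_module(net, "connectivity", target_size=40, rng_seed=1)
seeds = SeedSet("planted", module.members)

stats = lcc_significance(net, seeds, n_random=5000, rng_seed=3)
print(f"seed set: {seeds.s0} proteins; observed LCC size {stats.lcc_size}")
print(f"random same-size sets: LCC {stats.random_mean:.2f} +/- {stats.random_sd:.2f}")
print(f"z-score {stats.z_score:.2f}, empirical p {stats.empirical_p:.2g} "
      f"({stats.n_random} draws)")
print("z >> 1.6 means the set clusters far more than chance\n")

res = local_modularity(net, module.members)
print(f"local modularity R = {res.R:.4f} "
      f"(boundary {res.boundary_size}/{res.community_size} nodes)")
print("R near 0: the set is NOT a sharply bounded topological community, "
      "despite its significant clustering")
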