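"""Annotation-based validation of a ranked candidate list.

With no ground truth on real diseases, candidates are judged by shared
functional annotations: terms enriched in the seeds form a reference set,
and a sliding window along the ranking tracks how significantly the local
true-positive rate exceeds the background.  Here the annotations are
generated synthetically around the planted module, so the expected answer
is known by construction.
"""

import numpy as np

from diamonet import (
    DiamondConfig, SeedSet, enrich_seed_terms, make_synthetic_annotations,
    run_diamond, sample_module, synthetic_interactome, validate_ranking,
)

net = synthetic_interactome(n_nodes=1200, mean_degree=10, rng_seed=42)
module = sample_module(net, "connectivity", target_size=40, rng_seed=1)
rng = np.random.default_rng(2)
seeds = SeedSet("toy", frozenset(
    rng.choice(sorted(module.members), size=20, replace=False)))

ann = make_synthetic_annotations(net, module.members, n_terms=15,
                                 coverage=0.8, noise=0.1, rng_seed=3)
sig = enrich_seed_terms(ann, seeds, alpha_level=0.05)
print(f"{len(sig)}/{ann.n_terms} terms significantly enriched in the seeds "
      f"(Fisher exact, Bonferroni < 0.05)")

ranking = run_diamond(net, seeds, DiamondConfig(60))
result = validate_ranking(ranking, sig, ann)
print(f"seed true-positive rate: {result.seed_tp_rate:.2f}")
print("\niteration   TP in ranking so far   window p-value")
flags = result.tp_flags
for it in (10, 20, 40, 60):
    wp = dict(result.window_pvalues)[it]
    print(f"{it:9d}   {sum(flags[:it]):20d}   {wp:.3g}")
print("\nsmall window p early = candidates share the seeds' biology;"
      "\nthe p rising toward 1 marks where the module's evidence runs out")
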