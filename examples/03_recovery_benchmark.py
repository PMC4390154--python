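"""Planted-module recovery: remove a fraction of a module, grow it back,
and measure the recall of the removed members per iteration.

The recall curve is roughly insensitive to how much of the module was
removed, which is what lets the saturation point estimate the true-positive
rate on real diseases where the full module is unknown.
"""

from diamonet import run_recovery, sample_module, synthetic_interactome

net = synthetic_interactome(n_nodes=1200, mean_degree=10, rng_seed=42)
module = sample_module(net, "connectivity", target_size=40, rng_seed=1)

for frac in (0.25, 0.5, 0.75):
    exp = run_recovery(net, module, remove_fraction=frac,
                       n_iterations=40, rng_seed=4)
    marks = {10: None, 20: None, 40: None}
    for it in marks:
        marks[it] = exp.recall_at(it)
    print(f"removed {len(exp.removed):2d}/{module.size} ({int(frac*100)}%): "
          + ", ".join(f"recall@{it}={r:.2f}" for it, r in marks.items()))

print("\nrecall = recovered removed members / total removed;")
print("similar curves across removal fractions = recall reflects the module, "
      "not the completeness of the seed set")
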