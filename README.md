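# diamonet

Disease-module detection on protein interaction networks by **connectivity
significance** (the DIAMOnD approach), for computational biologists who have
a set of known disease genes and want a ranked, statistically grounded
expansion of it into the surrounding interactome neighborhood.

Proteins associated with the same disease cluster in specific neighborhoods
of the interactome, but those neighborhoods are *not* dense topological
communities: their local modularity R is near zero while their largest
connected component (LCC) is far larger than chance. What distinguishes
disease proteins is the statistical *significance* of their connections to
each other, not the number. For a network of `N` proteins with `s0` seeds,
the probability that a protein with degree `k` has exactly `k_s` links to
seeds under random placement is hypergeometric,

```
p(k, k_s) = C(s0, k_s) C(N - s0, k - k_s) / C(N, k)
```

and its connectivity p-value is the upper tail `P(X >= k_s)`. The detection
loop repeatedly scores all neighbors of the current module, absorbs the
protein with the smallest p-value, and iterates with the enlarged seed set;
the absorption order is the candidate ranking. A seed weight `alpha >= 1`
virtually duplicates each original seed with its interactions, biasing the
growth toward direct seed neighbors. P-values are evaluated in log space
(real disease sets reach values below 1e-23) and the per-iteration argmin
uses the dominance shortcut — at fixed `k_s` lower `k` always wins, at fixed
`k` higher `k_s` always wins — so exact p-values are only computed for a
shortlist.

The package also ships everything used to characterize and stress-test the
result: LCC significance against uniform random node sets, local modularity
R, planted synthetic modules (radius-2 *shells* and *connectivity-
significance* modules) with remove-and-recover benchmarks, network noise
models (uniform link pruning, degree-preserving stub rewiring), leave-one-
seed-out (N−1) robustness with deviation/persistence summaries, a random-
walk-with-restart baseline (restart probability 0.4), and annotation-based
(GMT) validation with a seed-width sliding-window Fisher test.

## Worked example

```python
import numpy as np
from diamonet import (DiamondConfig, SeedSet, module_lcc, run_diamond,
                      sample_module, synthetic_interactome)

net = synthetic_interactome(n_nodes=1200, mean_degree=10, rng_seed=42)
module = sample_module(net, "connectivity", target_size=40, rng_seed=1)
known = np.random.default_rng(2).choice(sorted(module.members), 20, replace=False)
seeds = SeedSet("toy disease", frozenset(known))

ranking = run_diamond(net, seeds, DiamondConfig(n_iterations=30))
for e in ranking.entries[:3]:
    print(e.iteration, e.gene, e.k, e.ks, f"{e.p_value:.3e}")
```

prints

```
1 g0024 22 4 3.395e-04
2 g0397 10 3 5.132e-04
3 g0120 14 3 1.711e-03
```

meaning: the first protein absorbed has degree 22 of which 4 links point at
the 20 seeds — a configuration with probability 3.4e-04 under random
placement, the most surprising connectivity of any module neighbor at that
step. On this planted benchmark 14 of the first 20 picks are true module
members, and `module_lcc(net, seeds, ranking, 30)` reports a 50-protein
module component that integrates 4 previously disconnected seeds. The
scripts in `examples/` walk through every capability (localization
statistics, recovery benchmarks, robustness, the random-walk comparison,
annotation validation) with printed, annotated output.

A thin command-line interface mirrors the library (`diamonet run`,
`lcc-stats`, `modularity`, `synth`, `recovery`, `perturb`, `nminus1`,
`rwr`, `validate`, `fixtures`); every command writes a TSV plus a JSON
manifest with parameters, seeds and input digests so deterministic runs
reproduce byte-identically.

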