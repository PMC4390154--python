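"""DIAMOnD module growth.

Starting from a set of seed proteins, the algorithm repeatedly
(i) evaluates the connectivity significance of every node adjacent to the
current module, (ii) ranks the candidates by p-value, (iii) adds the most
significantly connected one to the module, and (iv) iterates with the
enlarged seed set.  The order in which proteins are pulled in is their
relevance ranking.  The loop is fully deterministic: ties in p-value are
broken by higher seed-link count, then lower degree, then identifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .network import Interactome, SeedSet, lcc_nodes
from .significance import log_connectivity_pvalue, weighted_transform

logger = logging.getLogger(__name__)

__all__ = ["DiamondConfig", "DiamondEntry", "DiamondRanking", "run_diamond",
           "module_lcc", "write_ranking", "read_ranking"]


@dataclass(frozen=True)
class DiamondConfig:
    """Iteration budget and seed weight for a module-growth run.

    ``n_iterations`` defaults to 200, the module-size plateau observed on
    real diseases; ``alpha`` >= 1 up-weights the original seeds (``1`` =
    plain algorithm).
    """

    n_iterations: int = 200
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


class DiamondEntry(NamedTuple):
    iteration: int
    gene: str
    k: int
    ks: int
    p_value: float


@dataclass(frozen=True)
class DiamondRanking:
    """Ordered agglomeration record of one run."""

    entries: tuple[DiamondEntry, ...]
    seeds_used: SeedSet
    config: DiamondConfig = field(default_factory=DiamondConfig)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def top(self, n: int) -> list[str]:
        return [e.gene for e in self.entries[:n]]

    def __len__(self) -> int:
        return len(self.entries)


def run_diamond(
    net: Interactome,
    seeds: SeedSet | Iterable[str],
    config: DiamondConfig | None = None,
) -> DiamondRanking:
    """Grow a disease module by iterative connectivity significance.

    Candidates at each step are all non-module neighbors of the *current*
    module (so proteins without direct seed contact become reachable once
    intermediate nodes are absorbed).  Stops after ``config.n_iterations``
    or when no candidate remains, whichever comes first.
    """
    if config is None:
        config = DiamondConfig()
    if not isinstance(seeds, SeedSet):
        seeds = SeedSet.from_genes(net, seeds)
    if seeds.s0 == 0:
        raise ValueError("no seeds map onto the network")

    G = net.graph
    alpha = config.alpha
    N = net.n_nodes
    s0 = seeds.s0
    module = set(seeds.members)

    # ks bookkeeping: links into the module / into the weighted (original
    # seed) part of the module, maintained incrementally
    ks: dict[str, int] = {}
    ksw: dict[str, int] = {}
    for s in module:
        for nbr in G.adj[s]:
            if nbr in module:
                continue
            ks[nbr] = ks.get(nbr, 0) + 1
            ksw[nbr] = ksw.get(nbr, 0) + 1  # initial module = weighted seeds

    entries: list[DiamondEntry] = []
    for it in range(1, config.n_iterations + 1):
        if not ks:
            logger.warning(
                "candidate pool exhausted after %d iterations (budget %d)",
                it - 1, config.n_iterations,
            )
            break
        n_agg = len(module) - s0
        cache: dict[tuple[float, float], float] = {}
        # dominance pruning: per transformed-ks class keep the lowest
        # transformed k, then per k the highest ks; exact p only for these
        shortlist: dict[float, list[tuple[float, str, int, int]]] = {}
        for gene, ks_g in ks.items():
            k_g = G.degree[gene]
            _, sp, kp, ksp = weighted_transform(
                N, s0 if alpha > 1 else 0, n_agg if alpha > 1 else len(module),
                k_g, ks_g, ksw.get(gene, 0), alpha,
            )
            cls = shortlist.setdefault(ksp, [])
            if not cls or kp < cls[0][0]:
                shortlist[ksp] = [(kp, gene, k_g, ks_g)]
            elif kp == cls[0][0]:
                cls.append((kp, gene, k_g, ks_g))
        by_k: dict[float, list[tuple[float, str, int, int]]] = {}
        for ksp, cls in shortlist.items():
            for kp, gene, k_g, ks_g in cls:
                cur = by_k.setdefault(kp, [])
                if not cur or ksp > cur[0][0]:
                    by_k[kp] = [(ksp, gene, k_g, ks_g)]
                elif ksp == cur[0][0]:
                    cur.append((ksp, gene, k_g, ks_g))

        Np = N + (alpha - 1.0) * s0
        sp = alpha * s0 + n_agg
        best_key = None
        best = None
        for kp, cls in by_k.items():
            for ksp, gene, k_g, ks_g in cls:
                key2 = (kp, ksp)
                if key2 not in cache:
                    cache[key2] = log_connectivity_pvalue(Np, sp, kp, ksp)
                lp = cache[key2]
                cand_key = (lp, -ksp, kp, gene)
                if best_key is None or cand_key < best_key:
                    best_key = cand_key
                    best = (gene, k_g, ks_g, lp)

        gene, k_g, ks_g, lp = best
        entries.append(DiamondEntry(it, gene, k_g, ks_g, math.exp(lp)))
        module.add(gene)
        ks.pop(gene, None)
        ksw.pop(gene, None)
        for nbr in G.adj[gene]:
            if nbr in module:
                continue
            ks[nbr] = ks.get(nbr, 0) + 1

    return DiamondRanking(tuple(entries), seeds, config)


def module_lcc(
    net: Interactome,
    seeds: SeedSet,
    ranking: DiamondRanking,
    top_n: int,
) -> tuple[set[str], int]:
    """LCC of seeds plus the first ``top_n`` ranked genes.

    Returns the component's node set and the number of seed proteins it
    integrates that were *outside* the seed-only LCC — the previously
    disconnected seeds the agglomerated proteins reconnect.
    """
    if top_n > len(ranking):
        raise ValueError(f"top_n={top_n} exceeds ranking length {len(ranking)}")
    seed_lcc = lcc_nodes(net, seeds.members)
    nodes = set(seeds.members) | set(ranking.top(top_n))
    comp = lcc_nodes(net, nodes)
    integrated = sum(1 for s in seeds.members if s in comp and s not in seed_lcc)
    return comp, integrated


# ---------------------------------------------------------------------------
# serialization

_HEADER = ["iteration", "gene", "degree_k", "seed_links_ks", "p_value"]


def write_ranking(ranking: DiamondRanking, path: str | Path) -> None:
    """Write the ranking as TSV (p-values in scientific notation)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in ranking.entries:
            fh.write(f"{e.iteration}\t{e.gene}\t{e.k}\t{e.ks}\t{e.p_value:.6e}\n")


def read_ranking(path: str | Path) -> list[DiamondEntry]:
    """Read a ranking TSV written by :func:`write_ranking`."""
    entries = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"unexpected ranking header: {header}")
        for line in fh:
            it, gene, k, ks, p = line.rstrip("\n").split("\t")
            entries.append(DiamondEntry(int(it), gene, int(k), int(ks), float(p)))
    return entries
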