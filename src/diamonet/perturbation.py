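"""Network noise models and seed-set robustness.

Two perturbation ensembles probe how the detected modules react to
imperfect data: *pruned* networks (a fraction f of links removed
uniformly, emulating incompleteness) and *partially rewired* networks
(a fraction f of links split into stubs and reconnected uniformly — the
configuration model — emulating noise while preserving every node's
degree).  Seed-set robustness is assayed by the N-1 protocol: drop one
seed at a time, rerun the detector, and measure the deviation of the
resulting ranking from the original and how long it persists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diamond import DiamondConfig, DiamondRanking, run_diamond
from .network import Interactome, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationConfig",
    "RobustnessRecord",
    "prune_network",
    "rewire_network",
    "perturb_network",
    "n_minus_one",
    "ranking_overlap_curve",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Fraction of links to perturb, the noise mode, and the RNG seed."""

    f: float
    mode: str = "prune"  # "prune" or "rewire"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.mode not in ("prune", "rewire"):
            raise ValueError(f"mode must be 'prune' or 'rewire', got {self.mode!r}")


@dataclass(frozen=True)
class RobustnessRecord:
    """Effect of removing one seed: per-iteration deviation and persistence."""

    removed_seed: str
    deviation_curve: tuple[tuple[int, float], ...]
    persistence: float
    removed_seed_degree: int

    @property
    def max_deviation(self) -> float:
        return max((d for _, d in self.deviation_curve), default=0.0)


def _sorted_edges(net: Interactome) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in net.graph.edges)


def prune_network(net: Interactome, f: float, rng_seed: int = 0) -> Interactome:
    """Remove ``floor(f * E)`` uniformly chosen links; nodes are retained,
    so pruning can only isolate nodes, never drop them."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    edges = _sorted_edges(net)
    n_remove = int(np.floor(f * len(edges)))
    G = nx.Graph()
    G.add_nodes_from(net.graph.nodes)
    if n_remove == 0:
        G.add_edges_from(edges)
        return Interactome(G)
    rng = np.random.default_rng(rng_seed)
    drop = set(rng.choice(len(edges), size=n_remove, replace=False).tolist())
    G.add_edges_from(e for i, e in enumerate(edges) if i not in drop)
    return Interactome(G)


def rewire_network(
    net: Interactome,
    f: float,
    rng_seed: int = 0,
    max_shuffles: int = 100,
) -> Interactome:
    """Rewire ``floor(f * E)`` links by uniform stub reconnection.

    The selected links are split into stubs and re-paired uniformly;
    pairings that would create a self-loop or a duplicate edge are re-drawn
    (up to ``max_shuffles`` passes over the leftover stubs), with a
    double-edge-swap fallback for the rare stubborn remainder.  The degree
    sequence of the output is identical to the input's and the graph stays
    simple.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    edges = _sorted_edges(net)
    n_rewire = int(np.floor(f * len(edges)))
    G = nx.Graph()
    G.add_nodes_from(net.graph.nodes)
    if n_rewire == 0:
        G.add_edges_from(edges)
        return Interactome(G)
    rng = np.random.default_rng(rng_seed)
    chosen = set(rng.choice(len(edges), size=n_rewire, replace=False).tolist())
    kept = [e for i, e in enumerate(edges) if i not in chosen]
    G.add_edges_from(kept)

    stubs: list[str] = []
    for i in chosen:
        stubs.extend(edges[i])
    new_edges: list[tuple[str, str]] = []
    for _ in range(max_shuffles):
        if not stubs:
            break
        rng.shuffle(stubs)
        leftover: list[str] = []
        for j in range(0, len(stubs) - 1, 2):
            a, b = stubs[j], stubs[j + 1]
            if a == b or G.has_edge(a, b):
                leftover.extend((a, b))
            else:
                G.add_edge(a, b)
                new_edges.append((a, b))
        if len(stubs) % 2:  # odd leftover can't happen (stubs even), guard anyway
            leftover.append(stubs[-1])
        stubs = leftover

    if stubs:
        logger.info("stub pairing stalled with %d stubs; using swap fallback", len(stubs))
        _swap_fallback(G, rng, stubs, new_edges)
    return Interactome(G)


def _swap_fallback(G: nx.Graph, rng, stubs: list[str], new_edges: list[tuple[str, str]]) -> None:
    """Place remaining stub pairs by swapping against already rewired edges.

    For a blocked pair (a, b) pick a placed new edge (u, v) and try the
    cross pairings (a, u)+(b, v) or (a, v)+(b, u); both preserve the degree
    sequence.  Raises if no valid swap exists after many attempts
    (practically unreachable on non-degenerate graphs).
    """
    pairs = [(stubs[i], stubs[i + 1]) for i in range(0, len(stubs), 2)]
    for a, b in pairs:
        placed = False
        for _ in range(10_000):
            if not new_edges:
                break
            idx = int(rng.integers(len(new_edges)))
            u, v = new_edges[idx]
            for x, y, p, q in ((a, u, b, v), (a, v, b, u)):
                if x == y or p == q:
                    continue
                if G.has_edge(x, y) or G.has_edge(p, q) or {x, y} == {p, q}:
                    continue
                G.remove_edge(u, v)
                G.add_edge(x, y)
                G.add_edge(p, q)
                new_edges[idx] = (x, y)
                new_edges.append((p, q))
                placed = True
                break
            if placed:
                break
        if not placed:
            raise RuntimeError("rewiring fallback failed to place a stub pair")


def perturb_network(net: Interactome, cfg: PerturbationConfig) -> Interactome:
    """Apply the perturbation described by ``cfg``."""
    if cfg.mode == "prune":
        return prune_network(net, cfg.f, cfg.rng_seed)
    return rewire_network(net, cfg.f, cfg.rng_seed)


# ---------------------------------------------------------------------------
# seed-set robustness


def ranking_overlap_curve(original: list[str], perturbed: list[str]) -> list[float]:
    """Fraction of shared genes among the top-t of two rankings, per t."""
    n = min(len(original), len(perturbed))
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    out = []
    common = 0
    for t in range(n):
        a, b = original[t], perturbed[t]
        if a == b:
            common += 1
        else:
            if a in seen_b:
                common += 1
            if b in seen_a:
                common += 1
        seen_a.add(a)
        seen_b.add(b)
        out.append(common / (t + 1))
    return out


def n_minus_one(
    net: Interactome,
    seeds: SeedSet,
    config: DiamondConfig | None = None,
    original: DiamondRanking | None = None,
) -> list[RobustnessRecord]:
    """N-1 sensitivity: rerun the detector with each seed left out.

    Deviation at iteration t is ``1 - |top-t(original) ∩ top-t(leave-one-
    out)| / t``; persistence is the fraction of iterations with non-zero
    deviation.  Records are returned in sorted seed order.
    """
    if seeds.s0 < 2:
        raise ValueError("N-1 analysis needs at least 2 seeds")
    if config is None:
        config = DiamondConfig()
    if original is None:
        original = run_diamond(net, seeds, config)
    orig_genes = original.genes
    records = []
    for removed in sorted(seeds.members):
        reduced = SeedSet(seeds.name, seeds.members - {removed})
        pert = run_diamond(net, reduced, config)
        overlaps = ranking_overlap_curve(orig_genes, pert.genes)
        curve = tuple((t + 1, 1.0 - o) for t, o in enumerate(overlaps))
        n_dev = sum(1 for _, d in curve if d > 0)
        persistence = n_dev / len(curve) if curve else 0.0
        records.append(
            RobustnessRecord(removed, curve, persistence, net.degree(removed))
        )
    return records
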