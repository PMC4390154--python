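"""Interaction-network container and localization statistics.

The interactome is an undirected simple graph over opaque protein/gene
identifier strings (no identifier translation is performed).  On top of it
this module provides the localization statistics used to characterize
disease proteins: the size of the largest connected component (LCC) they
induce, its significance against same-size uniformly random node sets, and
the local modularity R of the community they form.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "SeedSet",
    "LCCStats",
    "ModularityResult",
    "load_edge_list",
    "load_seed_table",
    "lcc_size",
    "lcc_nodes",
    "lcc_significance",
    "local_modularity",
]


class Interactome:
    """Undirected simple interaction network.

    Thin wrapper around a :class:`networkx.Graph` that guarantees
    simplicity (no self-loops, no parallel edges) and exposes the
    quantities the connectivity statistics need (N, degrees, adjacency).
    """

    def __init__(self, graph: nx.Graph):
        if nx.number_of_selfloops(graph):
            raise ValueError("interactome must not contain self-loops")
        self.graph = graph

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> "Interactome":
        """Build from an iterable of identifier pairs, dropping self-loops
        and duplicate edges (counts are logged)."""
        G = nx.Graph()
        G.add_nodes_from(nodes)
        n_self = n_dup = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                G.add_node(a)
                continue
            if G.has_edge(a, b):
                n_dup += 1
                continue
            G.add_edge(a, b)
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        return cls(G)

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / n if n else 0.0

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:
        return f"Interactome(N={self.n_nodes}, E={self.n_edges})"


@dataclass(frozen=True)
class SeedSet:
    """A named set of seed proteins mapped onto a network.

    ``members`` are the identifiers present in the network; identifiers
    from the input that are absent are kept in ``unmapped`` for reporting.
    """

    name: str
    members: frozenset[str]
    unmapped: frozenset[str] = frozenset()

    @property
    def s0(self) -> int:
        return len(self.members)

    @classmethod
    def from_genes(cls, net: Interactome, genes: Iterable[str], name: str = "seeds") -> "SeedSet":
        genes = set(genes)
        members = frozenset(g for g in genes if g in net)
        unmapped = frozenset(genes - set(members))
        if unmapped:
            logger.info(
                "seed set %r: %d of %d identifiers not in the network",
                name, len(unmapped), len(genes),
            )
        return cls(name, members, unmapped)


@dataclass(frozen=True)
class LCCStats:
    """Observed LCC size of a seed set and its random-set null summary."""

    lcc_size: int
    z_score: float
    empirical_p: float
    n_random: int
    random_mean: float
    random_sd: float
    rng_seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class ModularityResult:
    """Local modularity R of a community (boundary sharpness, in [0, 1])."""

    R: float
    boundary_size: int
    community_size: int


# ---------------------------------------------------------------------------
# loading


def load_edge_list(path: str | Path, delimiter: str = "\t") -> Interactome:
    """Read a two-column edge list into an :class:`Interactome`.

    Lines starting with ``#`` and blank lines are ignored; extra columns
    are ignored; duplicate edges and self-loops are dropped with a logged
    count.  A non-comment line with fewer than two columns raises a
    ``ValueError`` naming the line number.
    """
    path = Path(path)

    def edge_iter():
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split(delimiter) if delimiter != " " else line.split()
                parts = [p.strip() for p in parts if p.strip()]
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                    )
                yield parts[0], parts[1]

    net = Interactome.from_edges(edge_iter())
    logger.info("loaded %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def load_seed_table(path: str | Path, delimiter: str = "\t") -> dict[str, set[str]]:
    """Read disease–gene associations.

    Two-column lines are ``disease_name<TAB>gene_id``; a file of
    single-column lines is accepted as one unnamed seed list (key ``""``).
    """
    path = Path(path)
    table: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split(delimiter) if p.strip()]
            if len(parts) >= 2:
                table.setdefault(parts[0], set()).add(parts[1])
            else:
                table.setdefault("", set()).add(parts[0])
    return table


# ---------------------------------------------------------------------------
# localization statistics


def _induced_lcc(adj, members: set[str]) -> set[str]:
    """Largest connected component of the subgraph induced by ``members``,
    by BFS restricted to the member set."""
    best: set[str] = set()
    unseen = set(members)
    while unseen:
        root = unseen.pop()
        comp = {root}
        queue = deque([root])
        while queue:
            v = queue.popleft()
            for u in adj[v]:
                if u in unseen:
                    unseen.discard(u)
                    comp.add(u)
                    queue.append(u)
        if len(comp) > len(best):
            best = comp
    return best


def lcc_nodes(net: Interactome, node_set: Iterable[str]) -> set[str]:
    """Members of the largest connected component induced by ``node_set``.

    Identifiers absent from the network are ignored; empty input gives an
    empty set.
    """
    members = {n for n in node_set if n in net}
    if not members:
        return set()
    return _induced_lcc(net.graph.adj, members)


def lcc_size(net: Interactome, node_set: Iterable[str]) -> int:
    """Size of the largest connected component induced by ``node_set``."""
    return len(lcc_nodes(net, node_set))


def lcc_significance(
    net: Interactome,
    seeds: SeedSet,
    n_random: int = 100_000,
    rng_seed: int = 0,
) -> LCCStats:
    """LCC size of the seeds versus same-size uniformly random node sets.

    Draws ``n_random`` node sets of size ``s0`` uniformly (no degree
    matching), records each induced LCC size, and reports the z-score and
    the empirical p-value ``(r + 1) / (n + 1)`` where ``r`` counts random
    LCC sizes at least as large as the observed one — so a never-exceeded
    observation reports ``p < 1/(n+1)`` rather than zero.  When the null
    has zero spread the z-score is reported as NaN with ``degenerate`` set.
    """
    if seeds.s0 == 0:
        raise ValueError("seed set is empty (s0 = 0); nothing to localize")
    observed = lcc_size(net, seeds.members)
    rng = np.random.default_rng(rng_seed)
    node_list = np.array(sorted(net.nodes))
    adj = net.graph.adj
    sizes = np.empty(n_random, dtype=np.int64)
    s0 = seeds.s0
    for i in range(n_random):
        draw = rng.choice(node_list, size=s0, replace=False)
        sizes[i] = len(_induced_lcc(adj, set(draw.tolist())))
    mean = float(sizes.mean())
    sd = float(sizes.std(ddof=0))
    degenerate = sd == 0.0
    z = math.nan if degenerate else (observed - mean) / sd
    if degenerate:
        logger.warning("degenerate LCC null (sd = 0); z-score undefined")
    r = int(np.sum(sizes >= observed))
    p = (r + 1) / (n_random + 1)
    return LCCStats(observed, z, p, n_random, mean, sd, rng_seed, degenerate)


def local_modularity(net: Interactome, community: Iterable[str]) -> ModularityResult:
    """Local modularity R of a community.

    The boundary B holds the community members with at least one link to a
    non-member.  R is the number of links attached to boundary nodes that
    stay inside the community divided by the total number of links attached
    to boundary nodes (each edge counted once).  A community with no
    boundary (fully separated) has R = 1 by convention.
    """
    community = set(community)
    if not community:
        raise ValueError("community must be non-empty")
    missing = [n for n in community if n not in net]
    if missing:
        raise ValueError(f"community members absent from the network: {sorted(missing)[:5]}")
    adj = net.graph.adj
    boundary = {v for v in community if any(u not in community for u in adj[v])}
    if not boundary:
        return ModularityResult(1.0, 0, len(community))
    inside = total = 0
    seen: set[tuple[str, str]] = set()
    for v in boundary:
        for u in adj[v]:
            e = (v, u) if v <= u else (u, v)
            if e in seen:
                continue
            seen.add(e)
            total += 1
            if u in community:
                inside += 1
    return ModularityResult(inside / total, len(boundary), len(community))
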