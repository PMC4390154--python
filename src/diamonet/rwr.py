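"""Random walk with restart (RWR) gene prioritization — the reference
diffusion method the connectivity-significance detector is compared to.

A walker moves to a uniformly random neighbor at each step and is reset to
a uniformly random seed with probability ``r`` (0.4 by default).  The visit
frequencies converge to the stationary distribution of

    p = r * u + (1 - r) * W p

with ``W`` the column-normalized adjacency matrix and ``u`` uniform over
the seeds; we compute that fixed point directly by power iteration, which
is the deterministic equivalent of simulating the walker.  Columns of
degree-0 nodes (possible after pruning) redirect their mass to the restart
vector so the scores always sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .network import Interactome, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["RWRConfig", "rwr_scores", "rwr_rank"]


@dataclass(frozen=True)
class RWRConfig:
    """Restart probability and convergence control for the walk."""

    restart_r: float = 0.4
    tolerance: float = 1e-10
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_r < 1.0:
            raise ValueError(f"restart_r must be in (0, 1), got {self.restart_r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def rwr_scores(
    net: Interactome,
    seeds: SeedSet,
    cfg: RWRConfig | None = None,
) -> dict[str, float]:
    """Stationary visit frequency of the restart walk, per node.

    Power iteration to L1 change below ``cfg.tolerance``; raises on
    non-convergence within ``cfg.max_steps`` (reporting the residual).
    Scores sum to 1.
    """
    if cfg is None:
        cfg = RWRConfig()
    if seeds.s0 == 0:
        raise ValueError("seed set is empty")
    nodelist = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodelist)}
    A = nx.to_scipy_sparse_array(net.graph, nodelist=nodelist, format="csc", dtype=float)
    deg = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    W = A @ sp.diags(inv)  # column-stochastic on non-dangling columns
    dangling = deg == 0

    u = np.zeros(len(nodelist))
    for s in seeds.members:
        u[index[s]] = 1.0 / seeds.s0

    r = cfg.restart_r
    p = u.copy()
    for _ in range(cfg.max_steps):
        leaked = float(p[dangling].sum())
        p_new = r * u + (1.0 - r) * (W @ p + leaked * u)
        delta = float(np.abs(p_new - p).sum())
        p = p_new
        if delta < cfg.tolerance:
            break
    else:
        raise RuntimeError(
            f"random walk did not converge in {cfg.max_steps} steps "
            f"(L1 residual {delta:.3e})"
        )
    return {n: float(p[i]) for i, n in enumerate(nodelist)}


def rwr_rank(scores: dict[str, float], seeds: SeedSet) -> list[str]:
    """Non-seed genes by descending visit frequency; ties lexicographic."""
    non_seeds = [g for g in scores if g not in seeds.members]
    if non_seeds and all(scores[g] == 0.0 for g in non_seeds):
        logger.warning("all non-seed scores are zero (seeds disconnected?); "
                       "ranking is lexicographic")
    return sorted(non_seeds, key=lambda g: (-scores[g], g))
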