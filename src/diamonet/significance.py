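"""Hypergeometric connectivity significance.

The central statistic: given a network of ``N`` nodes of which ``s0`` are
seeds, the probability that a node with degree ``k`` has exactly ``ks``
links to seeds under random placement is hypergeometric,

    p(k, ks) = C(s0, ks) * C(N - s0, k - ks) / C(N, k)

and the *connectivity p-value* is the upper tail P(X >= ks).  Everything is
evaluated in log-space (log-gamma binomials) so that p-values far below the
double-precision underflow of naive products (observed values reach 1e-23
and smaller on real interactomes) remain representable.

A seed weight ``alpha >= 1`` generalizes the statistic by virtually
duplicating every original seed ``alpha`` times while keeping its
interactions; nodes agglomerated during module growth keep weight 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SignificanceQuery",
    "CandidateScore",
    "hypergeom_pmf",
    "log_hypergeom_pmf",
    "connectivity_pvalue",
    "log_connectivity_pvalue",
    "weighted_pvalue",
    "weighted_transform",
    "rank_candidates",
    "best_candidate",
]


def _log_binom(n: float, k: float) -> float:
    """log C(n, k) via log-gamma; real-valued n is allowed (generalized
    binomial), k must satisfy 0 <= k <= n."""
    return float(gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0))


@dataclass(frozen=True)
class SignificanceQuery:
    """Parameters of one connectivity-significance evaluation.

    N
        number of nodes in the network (after any seed weighting).
    s0
        current number of seed nodes; real-valued once ``alpha`` weighting
        is applied.
    k
        degree of the candidate node.
    ks
        number of the candidate's links that point to seed nodes.
    alpha
        seed weight, ``>= 1``; ``1`` recovers the plain statistic.
    """

    N: float
    s0: float
    k: float
    ks: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if not 0 <= self.s0 <= self.N:
            raise ValueError(f"s0 must satisfy 0 <= s0 <= N, got s0={self.s0}")
        if not 0 <= self.k <= self.N - 1 + 1e-9:
            raise ValueError(f"k must satisfy 0 <= k <= N-1, got k={self.k}")
        if self.ks < 0 or self.ks > self.k + 1e-9:
            raise ValueError(f"ks must satisfy 0 <= ks <= k, got ks={self.ks}")
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")


@dataclass(frozen=True, order=False)
class CandidateScore:
    """One scored candidate: degree, seed links and connectivity p-value."""

    gene: str
    k: int
    ks: int
    p_value: float
    log_p: float = field(default=0.0)

    def sort_key(self):
        # ascending p, ties: higher ks, lower k, lexicographic identifier
        return (self.log_p, -self.ks, self.k, self.gene)


def log_hypergeom_pmf(N: float, s0: float, k: float, ks: float) -> float:
    """log of the hypergeometric pmf; ``-inf`` for impossible (k, ks)."""
    if ks > s0 or (k - ks) > (N - s0):
        return -math.inf
    return (
        _log_binom(s0, ks)
        + _log_binom(N - s0, k - ks)
        - _log_binom(N, k)
    )


def hypergeom_pmf(q: SignificanceQuery) -> float:
    """Probability that a degree-k node has exactly ks links to the s0 seeds."""
    lp = log_hypergeom_pmf(q.N, q.s0, q.k, q.ks)
    return 0.0 if lp == -math.inf else math.exp(lp)


def log_connectivity_pvalue(N: float, s0: float, k: float, ks: float) -> float:
    """log of P(X >= ks) for X hypergeometric(N, s0, k).

    Summed in log-space with ``logsumexp`` so tails down to ~1e-300 in the
    exponent are handled stably.  Returns 0.0 (p = 1) for ks <= 0.
    """
    if ks <= 0:
        return 0.0
    hi = min(k, math.floor(s0 + 1e-9))
    kis = np.arange(ks, hi + 1, dtype=float)
    if kis.size == 0:
        return -math.inf
    # vectorized log-pmf over the tail support
    terms = (
        gammaln(s0 + 1.0)
        - gammaln(kis + 1.0)
        - gammaln(s0 - kis + 1.0)
        + gammaln(N - s0 + 1.0)
        - gammaln(k - kis + 1.0)
        - gammaln(N - s0 - (k - kis) + 1.0)
        - _log_binom(N, k)
    )
    # drop combinatorially impossible terms (k - ki > N - s0)
    terms = terms[(k - kis) <= (N - s0) + 1e-9]
    if terms.size == 0:
        return -math.inf
    m = float(np.max(terms))
    return min(0.0, m + math.log(float(np.sum(np.exp(terms - m)))))


def connectivity_pvalue(q: SignificanceQuery) -> float:
    """Upper-tail connectivity p-value P(X >= ks); in (0, 1]."""
    lp = log_connectivity_pvalue(q.N, q.s0, q.k, q.ks)
    return math.exp(lp)


def weighted_transform(
    N: float,
    s0_orig: float,
    n_agglomerated: float,
    k: float,
    ks_total: float,
    ks_weighted: float,
    alpha: float,
) -> tuple[float, float, float, float]:
    """Seed-duplication transform for a seed weight ``alpha``.

    Each of the ``s0_orig`` original seeds is virtually present ``alpha``
    times with all its interactions; agglomerated nodes keep weight 1.
    ``ks_weighted`` counts the candidate's links to weight-``alpha`` seeds
    (``ks_total`` counts links to the whole current module).
    Returns the transformed ``(N', s', k', ks')``.
    """
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    extra = (alpha - 1.0) * ks_weighted
    return (
        N + (alpha - 1.0) * s0_orig,
        alpha * s0_orig + n_agglomerated,
        k + extra,
        ks_total + extra,
    )


def weighted_pvalue(q: SignificanceQuery, ks_weighted: float | None = None) -> float:
    """Connectivity p-value under the seed weight ``q.alpha``.

    With no agglomerated nodes (the standalone case) every seed link is a
    link to a weight-alpha seed, so ``ks_weighted`` defaults to ``q.ks``.
    """
    if ks_weighted is None:
        ks_weighted = q.ks
    Np, sp, kp, ksp = weighted_transform(
        q.N, q.s0, 0.0, q.k, q.ks, ks_weighted, q.alpha
    )
    return math.exp(log_connectivity_pvalue(Np, sp, kp, ksp))


# ---------------------------------------------------------------------------
# candidate ranking


def _candidate_counts(net, module: set[str], weights: Mapping[str, float] | None):
    """(gene, k, ks_total, ks_weighted) for every node adjacent to the module."""
    G = net.graph
    out = []
    seen = set()
    for m in module:
        for nbr in G.adj[m]:
            if nbr in module or nbr in seen:
                continue
            seen.add(nbr)
            ks = ksw = 0
            for u in G.adj[nbr]:
                if u in module:
                    ks += 1
                    if weights is not None and weights.get(u, 1.0) > 1.0:
                        ksw += 1
            out.append((nbr, G.degree[nbr], ks, ksw))
    return out


def _alpha_of(weights: Mapping[str, float] | None) -> float:
    if not weights:
        return 1.0
    vals = {w for w in weights.values() if w > 1.0}
    if not vals:
        return 1.0
    if len(vals) > 1:
        raise ValueError("mixed seed weights are not supported; use one alpha")
    return float(vals.pop())


def rank_candidates(
    net,
    module: Iterable[str],
    weights: Mapping[str, float] | None = None,
) -> list[CandidateScore]:
    """All neighbors of ``module`` ordered by ascending connectivity p-value.

    ``weights`` maps nodes to a seed weight (alpha for weighted seeds, 1
    otherwise).  Exact p-values are computed once per distinct transformed
    ``(k, ks)`` pair; the returned order equals the exhaustive per-candidate
    computation, with ties broken by higher ks, then lower k, then
    identifier.
    """
    module = set(module)
    if not module:
        raise ValueError("module must be non-empty")
    alpha = _alpha_of(weights)
    n_weighted = (
        sum(1 for m in module if weights and weights.get(m, 1.0) > 1.0)
        if weights
        else 0
    )
    n_plain = len(module) - n_weighted
    N = net.n_nodes
    cache: dict[tuple[float, float], float] = {}
    scores = []
    for gene, k, ks, ksw in _candidate_counts(net, module, weights):
        Np, sp, kp, ksp = weighted_transform(N, n_weighted, n_plain, k, ks, ksw, alpha)
        if alpha == 1.0:
            # unweighted: s' counts the whole module
            sp = len(module)
        key = (kp, ksp)
        if key not in cache:
            cache[key] = log_connectivity_pvalue(Np, sp, kp, ksp)
        lp = cache[key]
        scores.append(CandidateScore(gene, int(k), int(ks), math.exp(lp), lp))
    scores.sort(key=CandidateScore.sort_key)
    return scores


def best_candidate(
    net,
    module: Iterable[str],
    weights: Mapping[str, float] | None = None,
) -> CandidateScore | None:
    """Lowest-p-value candidate via dominance pruning.

    At fixed ks the p-value increases with k, and at fixed k it decreases
    with ks.  So within each ks class only the lowest-k candidates can win,
    and of those, within each k class only the highest-ks one.  Exact
    p-values are evaluated only for this shortlist (at most one per ks
    class), which is the efficient per-iteration path of the module-growth
    loop.  Returns ``None`` when the module has no outside neighbor.
    """
    module = set(module)
    if not module:
        raise ValueError("module must be non-empty")
    alpha = _alpha_of(weights)
    n_weighted = (
        sum(1 for m in module if weights and weights.get(m, 1.0) > 1.0)
        if weights
        else 0
    )
    n_plain = len(module) - n_weighted
    N = net.n_nodes
    counts = _candidate_counts(net, module, weights)
    if not counts:
        return None

    # transformed (k', ks') per candidate
    items = []
    for gene, k, ks, ksw in counts:
        Np, sp, kp, ksp = weighted_transform(N, n_weighted, n_plain, k, ks, ksw, alpha)
        if alpha == 1.0:
            sp = len(module)
        items.append((gene, int(k), int(ks), kp, ksp, Np, sp))

    # step 1: per ks' class keep the lowest k' (all genes attaining it,
    # for deterministic tie-breaks)
    by_ks: dict[float, list] = {}
    for it in items:
        cls = by_ks.setdefault(it[4], [])
        if not cls or it[3] < cls[0][3]:
            by_ks[it[4]] = [it]
        elif it[3] == cls[0][3]:
            cls.append(it)
    # step 2: per surviving k' keep the highest ks'
    by_k: dict[float, list] = {}
    for cls in by_ks.values():
        for it in cls:
            cur = by_k.setdefault(it[3], [])
            if not cur or it[4] > cur[0][4]:
                by_k[it[3]] = [it]
            elif it[4] == cur[0][4]:
                cur.append(it)

    best = None
    best_key = None
    for cls in by_k.values():
        for gene, k, ks, kp, ksp, Np, sp in cls:
            lp = log_connectivity_pvalue(Np, sp, kp, ksp)
            key = (lp, -ksp, kp, gene)
            if best_key is None or key < best_key:
                best_key = key
                best = CandidateScore(gene, k, ks, math.exp(lp), lp)
    return best
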