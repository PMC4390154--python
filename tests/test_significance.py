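"""Connectivity significance against exact rational oracles.

The oracles use integer combinatorics (fractions.Fraction + math.comb) and
explicit graph materialization, independent of the log-space evaluation
they check.
"""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diamonet import (
    Interactome,
    best_candidate,
    connectivity_pvalue,
    hypergeom_pmf,
    rank_candidates,
    weighted_pvalue,
)
from diamonet.significance import SignificanceQuery as Q
from diamonet.significance import log_connectivity_pvalue

from conftest import random_net


def exact_pmf(N: int, s0: int, k: int, ks: int) -> Fraction:
    if ks > s0 or k - ks > N - s0:
        return Fraction(0)
    return Fraction(math.comb(s0, ks) * math.comb(N - s0, k - ks), math.comb(N, k))


def exact_pvalue(N: int, s0: int, k: int, ks: int) -> Fraction:
    return sum(
        (exact_pmf(N, s0, k, ki) for ki in range(ks, min(k, s0) + 1)),
        Fraction(0),
    )


class TestPmf:
    def test_hand_example(self):
        # urn of 10 with 3 marked; draw 4, see 2 marked: C(3,2)C(7,2)/C(10,4)
        assert hypergeom_pmf(Q(10, 3, 4, 2)) == pytest.approx(63 / 210, rel=1e-12)

    def test_no_seeds_certain_zero_links(self):
        for k in (0, 1, 5):
            assert hypergeom_pmf(Q(10, 0, k, 0)) == pytest.approx(1.0)

    def test_impossible_configurations_are_zero(self):
        assert hypergeom_pmf(Q(10, 3, 4, 4)) == 0.0  # ks > s0
        assert hypergeom_pmf(Q(10, 9, 5, 0)) == 0.0  # k - ks > N - s0

    def test_normalization_sweep(self):
        """Sum over ks of the pmf is 1 to 1e-12 for every N <= 60."""
        for N in range(1, 61):
            for s0 in range(0, N + 1, max(1, N // 7)):
                for k in range(0, N, max(1, N // 7)):
                    total = sum(
                        hypergeom_pmf(Q(N, s0, k, ks)) for ks in range(0, k + 1)
                    )
                    assert total == pytest.approx(1.0, abs=1e-12), (N, s0, k)

    def test_matches_exact_rationals_full_N40(self):
        """Log-space pmf vs Fraction arithmetic on all (N <= 40) queries."""
        for N in range(2, 41, 2):
            for s0 in range(0, N + 1):
                for k in range(0, N):
                    for ks in range(0, min(k, s0) + 1):
                        got = hypergeom_pmf(Q(N, s0, k, ks))
                        want = float(exact_pmf(N, s0, k, ks))
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-300)


class TestPvalue:
    def test_ks_zero_is_one(self):
        for N, s0, k in [(10, 3, 4), (50, 10, 20), (5, 5, 4)]:
            assert connectivity_pvalue(Q(N, s0, k, 0)) == 1.0

    def test_hand_sums(self):
        assert connectivity_pvalue(Q(10, 3, 4, 2)) == pytest.approx(70 / 210, rel=1e-10)
        assert connectivity_pvalue(Q(10, 3, 3, 3)) == pytest.approx(1 / 120, rel=1e-10)

    def test_matches_exact_rationals(self):
        for N in range(2, 41, 3):
            for s0 in range(1, N + 1, 2):
                for k in range(1, N, 2):
                    for ks in range(0, min(k, s0) + 1):
                        got = connectivity_pvalue(Q(N, s0, k, ks))
                        want = float(exact_pvalue(N, s0, k, ks))
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-300)

    def test_deep_tail_representable(self):
        """Extreme configurations stay finite in log-space far below the
        smallest normal double product chain."""
        lp = log_connectivity_pvalue(13460, 45, 45, 45)
        assert -500 < lp < -50
        assert math.exp(lp) >= 0.0

    def test_monotonicity_lemma(self):
        """p strictly decreases in ks at fixed (N, s0, k) and strictly
        increases in k at fixed (N, s0, ks >= 1) — the pruning lemma.

        Strictness is asserted on exact rationals (the float evaluation
        saturates at 1 - eps for large k); the float path must track the
        exact value to 1e-10 relative, which the oracle tests above cover.
        """
        N = 60
        for s0 in (5, 12, 25):
            for k in range(2, 40, 3):
                prev = None
                for ks in range(1, min(k, s0) + 1):
                    p = exact_pvalue(N, s0, k, ks)
                    if ks <= k - (N - s0):
                        # that many seed links are forced: tail is still 1
                        assert p == 1, (s0, k, ks)
                        continue
                    if prev is not None:
                        assert p < prev, (s0, k, ks)
                    prev = p
            for ks in (1, 3, 5):
                prev = None
                for k in range(ks, N - 1, 2):
                    if ks > min(k, s0):
                        continue
                    p = exact_pvalue(N, s0, k, ks)
                    if k <= N - s0 + ks - 1:
                        if prev is not None:
                            assert p > prev, (s0, k, ks)
                        prev = p
                    else:
                        # beyond this point ks links to seeds are forced
                        assert p == 1, (s0, k, ks)

    def test_bound_violations_raise(self):
        with pytest.raises(ValueError, match="N"):
            Q(0, 0, 0, 0)
        with pytest.raises(ValueError, match="s0"):
            Q(10, 11, 3, 1)
        with pytest.raises(ValueError, match="k "):
            Q(10, 3, 10, 1)
        with pytest.raises(ValueError, match="ks"):
            Q(10, 3, 4, 5)
        with pytest.raises(ValueError, match="alpha"):
            Q(10, 3, 4, 2, alpha=0.5)


def duplicated_graph_pvalue(G: nx.Graph, seeds: set, candidate, alpha: int) -> float:
    """Oracle for the seed weight: materialize alpha - 1 extra copies of
    every seed with its interactions and evaluate the plain statistic."""
    H = G.copy()
    for s in seeds:
        for c in range(alpha - 1):
            copy = f"{s}__dup{c}"
            H.add_node(copy)
            for nbr in G.adj[s]:
                H.add_edge(copy, nbr)
    all_seeds = set(seeds) | {
        f"{s}__dup{c}" for s in seeds for c in range(alpha - 1)
    }
    k = H.degree[candidate]
    ks = sum(1 for u in H.adj[candidate] if u in all_seeds)
    return float(exact_pvalue(H.number_of_nodes(), len(all_seeds), k, ks))


class TestWeighted:
    def test_alpha_one_is_identity(self):
        for N, s0, k, ks in [(10, 3, 4, 2), (30, 6, 10, 3), (50, 10, 5, 0)]:
            assert weighted_pvalue(Q(N, s0, k, ks, alpha=1.0)) == pytest.approx(
                connectivity_pvalue(Q(N, s0, k, ks)), rel=1e-12
            )

    def test_no_seed_links_is_one(self):
        for alpha in (1.0, 2.0, 3.5):
            assert weighted_pvalue(Q(20, 5, 6, 0, alpha=alpha)) == 1.0

    @given(seed=st.integers(0, 100), alpha=st.sampled_from([2, 3]))
    @settings(max_examples=40, deadline=None)
    def test_integer_alpha_equals_duplicated_graph(self, seed, alpha):
        G = nx.gnp_random_graph(15, 0.3, seed=seed)
        rng = np.random.default_rng(seed)
        nodes = list(G.nodes)
        seeds = set(rng.choice(nodes, size=4, replace=False).tolist())
        candidates = [n for n in nodes if n not in seeds]
        cand = candidates[int(rng.integers(len(candidates)))]
        k = G.degree[cand]
        if k == 0:
            return
        ks = sum(1 for u in G.adj[cand] if u in seeds)
        got = weighted_pvalue(Q(G.number_of_nodes(), len(seeds), k, ks, alpha=alpha))
        want = duplicated_graph_pvalue(G, seeds, cand, alpha)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-300)


def exhaustive_ranking(net, module):
    """Brute-force oracle: p-value for every candidate, full sort."""
    module = set(module)
    N = net.n_nodes
    s = len(module)
    cands = set()
    for m in module:
        cands.update(u for u in net.graph.adj[m] if u not in module)
    rows = []
    for c in sorted(cands):
        k = net.graph.degree[c]
        ks = sum(1 for u in net.graph.adj[c] if u in module)
        p = exact_pvalue(N, s, k, ks)
        rows.append((c, k, ks, p))
    rows.sort(key=lambda r: (r[3], -r[2], r[1], r[0]))
    return rows


class TestRanking:
    def test_higher_ks_wins_at_equal_degree(self):
        # star-ish toy: X has 3 seed links, Y has 1, equal degree 3
        edges = [("s1", "X"), ("s2", "X"), ("s3", "X"), ("s1", "Y"),
                 ("Y", "o1"), ("Y", "o2")]
        net = Interactome.from_edges(edges)
        ranked = rank_candidates(net, {"s1", "s2", "s3"})
        assert ranked[0].gene == "X"

    def test_lower_degree_wins_at_equal_ks(self):
        edges = [("s1", "X"), ("s1", "Y")]
        edges += [("Y", f"o{i}") for i in range(8)]
        edges += [("X", "p1")]
        net = Interactome.from_edges(edges)
        ranked = rank_candidates(net, {"s1"})
        assert ranked[0].gene == "X"

    def test_empty_module_rejected(self, triangle):
        with pytest.raises(ValueError):
            rank_candidates(triangle, set())

    @given(seed=st.integers(0, 400))
    @settings(max_examples=100, deadline=None)
    def test_full_ranking_matches_exhaustive_oracle(self, seed):
        net = random_net(50, 0.08, seed=seed)
        rng = np.random.default_rng(seed)
        nodes = sorted(net.nodes)
        module = set(rng.choice(nodes, size=6, replace=False).tolist())
        want = exhaustive_ranking(net, module)
        got = rank_candidates(net, module)
        assert [c.gene for c in got] == [r[0] for r in want]
        for c, (gene, k, ks, p) in zip(got, want):
            assert (c.k, c.ks) == (k, ks)
            assert c.p_value == pytest.approx(float(p), rel=1e-9, abs=1e-300)

    @given(seed=st.integers(1000, 1400))
    @settings(max_examples=100, deadline=None)
    def test_pruned_best_equals_exhaustive_argmin(self, seed):
        net = random_net(50, 0.08, seed=seed)
        rng = np.random.default_rng(seed)
        nodes = sorted(net.nodes)
        module = set(rng.choice(nodes, size=5, replace=False).tolist())
        want = exhaustive_ranking(net, module)
        got = best_candidate(net, module)
        if not want:
            assert got is None
        else:
            assert got.gene == want[0][0]
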