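"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's search/statistics code paths: the
hypergeometric oracle enumerates the pmf with exact integer binomials, and
the subgraph oracle enumerates every connected vertex subset by bitmask.
"""

from __future__ import annotations

import math
from itertools import combinations

from pathgwas.subnetwork_search import module_from_genes


def hypergeom_two_sided_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """Two-sided hypergeometric p by full pmf enumeration (exact rationals)."""
    denom = math.comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    pmf = {x: math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)}
    p_enrich = sum(v for x, v in pmf.items() if x >= k) / denom
    p_deplete = sum(v for x, v in pmf.items() if x <= k) / denom
    return min(1.0, 2.0 * min(p_enrich, p_deplete))


def connected_subsets(adjacency: dict[str, set[str]], max_size: int):
    """Yield every connected vertex subset up to max_size (bitmask BFS)."""
    nodes = sorted(adjacency)
    index = {n: i for i, n in enumerate(nodes)}
    adj_mask = [0] * len(nodes)
    for n, nbs in adjacency.items():
        for nb in nbs:
            adj_mask[index[n]] |= 1 << index[nb]
    n_bits = len(nodes)
    for mask in range(1, 1 << n_bits):
        size = mask.bit_count()
        if size > max_size:
            continue
        # BFS over bits to check connectivity
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                bit = m & -m
                m ^= bit
                nxt |= adj_mask[bit.bit_length() - 1]
            frontier = nxt & mask & ~seen
            seen |= frontier
        if seen == mask:
            yield frozenset(nodes[i] for i in range(n_bits) if mask >> i & 1)


def exhaustive_best_module(network, table, bg, max_size: int):
    """Best combined score over every connected subgraph (≤ max_size)."""
    adjacency = {
        n: {nb for nb in nbs if nb in table.z}
        for n, nbs in network.adjacency().items()
        if n in table.z
    }
    best = None
    for genes in connected_subsets(adjacency, max_size):
        mod = module_from_genes(genes, table, bg)
        if best is None or mod.combined_score > best.combined_score:
            best = mod
    return best
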