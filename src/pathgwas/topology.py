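"""Degree-distribution diagnostics: power-law fit, Erdős–Rényi
randomization and a Poisson dispersion check."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from pathgwas.errors import ValidationError
from pathgwas.io_formats import PpiNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram of node degrees (degree ≥ 1); isolated nodes counted apart."""

    counts: Mapping[int, int]  # degree -> number of nodes
    n_nodes: int
    n_edges: int
    n_isolated: int

    def degrees(self) -> np.ndarray:
        """Expand the histogram back into a per-node degree array."""
        out = []
        for k in sorted(self.counts):
            out.extend([k] * self.counts[k])
        out.extend([0] * self.n_isolated)
        return np.array(out, dtype=float)


@dataclass(frozen=True)
class PowerLawFit:
    a: float
    gamma: float
    r_squared: float
    correlation: float


def degree_distribution(network: PpiNetwork) -> DegreeDistribution:
    """Exact degree histogram of a network."""
    deg = network.degree()
    counts: dict[int, int] = {}
    isolated = 0
    for _, d in deg.items():
        if d == 0:
            isolated += 1
        else:
            counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(
        counts=counts,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        n_isolated=isolated,
    )


def fit_power_law(dist: DegreeDistribution | Mapping[int, int]) -> PowerLawFit:
    """OLS fit of log10(count) on log10(degree): count(k) ≈ a·k^(−gamma).

    Raw counts (not frequencies) are fitted and degrees with zero count are
    excluded (log undefined).  Requires ≥ 3 support points.
    """
    counts = dist.counts if isinstance(dist, DegreeDistribution) else dist
    pts = [(k, c) for k, c in counts.items() if c > 0 and k >= 1]
    if len(pts) < 3:
        raise ValidationError(
            f"power-law fit needs >= 3 distinct degrees, got {len(pts)}"
        )
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    res = stats.linregress(x, y)
    return PowerLawFit(
        a=float(10.0**res.intercept),
        gamma=float(-res.slope),
        r_squared=float(res.rvalue**2),
        correlation=float(res.rvalue),
    )


def erdos_renyi_randomize(network: PpiNetwork, seed: int = 0) -> PpiNetwork:
    """Random simple G(n, m) graph with the same node and edge counts.

    Node labels are preserved so downstream comparisons stay aligned.
    """
    nodes = sorted(network.nodes)
    n, m = len(nodes), network.n_edges
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValidationError(f"cannot place {m} edges on {n} nodes")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    while len(edges) < m:
        draw = rng.integers(0, n, size=2 * (m - len(edges) + 8))
        for i in range(0, draw.size, 2):
            u, v = int(draw[i]), int(draw[i + 1])
            if u == v:
                continue
            edge = (u, v) if u < v else (v, u)
            edges.add(edge)
            if len(edges) == m:
                break
    return PpiNetwork.from_edges(
        [(nodes[u], nodes[v]) for u, v in edges], extra_nodes=nodes
    )


def poisson_check(dist: DegreeDistribution) -> tuple[float, float, float]:
    """Sample mean, variance and dispersion ratio of the degree sequence.

    Ratio ≈ 1 is Poisson-like (random network); ratio ≫ 1 flags heavy
    tails (hubs).  A regular graph has variance 0 and ratio 0.
    """
    degrees = dist.degrees()
    if degrees.size == 0:
        raise ValidationError("empty degree sequence")
    mean = float(degrees.mean())
    var = float(degrees.var())
    ratio = var / mean if mean > 0 else math.nan
    return mean, var, ratio
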