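"""Active sub-network discovery on a PPI network.

Gene-wise weighted p-values are converted to z-scores; a connected set of k
genes is scored ``S = sum(z_i) / sqrt(k)``, standardized against a
Monte-Carlo background of random size-k gene sets, combined across the two
evidence attributes, and greedily grown from every seed node.  Modules with
a combined score above the significance threshold (default 3, i.e. three
standard deviations above the randomized mean) are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from pathgwas.errors import ValidationError
from pathgwas.io_formats import PpiNetwork, TRACKS

logger = logging.getLogger(__name__)

_CLAMP_LO = 1e-15
_CLAMP_HI = 1.0 - 1e-15

#: Expected maximum of j i.i.d. standard normal variables, j = 1..10.
#: Precomputed (E[max_j] = ∫ z·j·φ(z)·Φ(z)^(j−1) dz); used as the rank
#: penalty when combining attribute scores.
EXPECTED_MAX_ORDER_STAT: tuple[float, ...] = (
    0.0,
    0.5641895835477563,
    0.8462843753216345,
    1.0293753730039641,
    1.1629644736405196,
    1.2672063606114712,
    1.3521783756069043,
    1.4236003060452777,
    1.4850131622092370,
    1.5387527308351728,
)


def expected_max_order_stat(j: int) -> float:
    """E[max of j i.i.d. N(0,1)] from the shipped constant table."""
    if j < 1:
        raise ValidationError(f"order statistic index must be >= 1, got {j}")
    if j <= len(EXPECTED_MAX_ORDER_STAT):
        return EXPECTED_MAX_ORDER_STAT[j - 1]
    # asymptotic fallback for j beyond the table (never hit with 2 attributes)
    z = stats.norm.ppf(1.0 - 1.0 / j)
    return float(z + (math.log(math.log(j)) + math.log(4 * math.pi)) / (2 * z or 1.0))


def pvalue_to_z(pw: float) -> float:
    """z = Φ⁻¹(1 − pw); pw clamped into [1e-15, 1−1e-15] before transform.

    Smaller weighted p-values map to larger z, so high-priority genes score
    high.  pw ≤ 0 is a validation error.
    """
    if pw <= 0.0:
        raise ValidationError(f"weighted p-value must be > 0, got {pw}")
    clamped = min(max(pw, _CLAMP_LO), _CLAMP_HI)
    return float(stats.norm.isf(clamped))


@dataclass(frozen=True)
class NodeScoreTable:
    """Per-gene z-scores on both attributes, restricted to PPI nodes."""

    z: Mapping[str, tuple[float, float]]  # gene -> (z_spot, z_fsnp)

    def __post_init__(self) -> None:
        for gene, (zs, zf) in self.z.items():
            if not (math.isfinite(zs) and math.isfinite(zf)):
                raise ValidationError(f"non-finite z-score for {gene!r}")

    @classmethod
    def from_gene_scores(cls, gene_scores, network: PpiNetwork) -> "NodeScoreTable":
        """Build the table from GeneScore records, keeping only PPI nodes."""
        z: dict[str, tuple[float, float]] = {}
        for gs in gene_scores:
            if gs.gene in network.nodes:
                z[gs.gene] = (pvalue_to_z(gs.spot_pw), pvalue_to_z(gs.fsnp_pw))
        dropped = sum(1 for gs in gene_scores if gs.gene not in network.nodes)
        if dropped:
            logger.info("%d scored gene(s) absent from the PPI network", dropped)
        return cls(z=dict(z))

    @property
    def genes(self) -> list[str]:
        return sorted(self.z)

    def __len__(self) -> int:
        return len(self.z)

    def attribute_array(self, attr: str) -> np.ndarray:
        idx = TRACKS.index(attr)
        return np.array([self.z[g][idx] for g in self.genes], dtype=float)


@dataclass(frozen=True)
class BackgroundTable:
    """Monte-Carlo mean/sd of raw scores of random size-k gene sets."""

    means: Mapping[int, float]
    sds: Mapping[int, float]
    n_samples: int
    seed: int

    def __contains__(self, k: int) -> bool:
        return k in self.means

    def sizes(self) -> list[int]:
        return sorted(self.means)


@dataclass(frozen=True)
class Module:
    """A connected sub-network with raw, calibrated and combined scores."""

    genes: frozenset[str]
    raw_scores: Mapping[str, float]
    calibrated_scores: Mapping[str, float]
    combined_score: float
    seed_gene: str

    @property
    def k(self) -> int:
        return len(self.genes)


def score_subnetwork(zs: Sequence[float]) -> float:
    """Raw aggregate score S = Σ z_i / √k of a k-gene set."""
    k = len(zs)
    if k < 1:
        raise ValidationError("cannot score an empty gene set")
    return float(sum(zs) / math.sqrt(k))


def calibrate_background(
    scores: Sequence[float] | np.ndarray,
    sizes: Iterable[int],
    n_samples: int = 10_000,
    seed: int = 0,
) -> BackgroundTable:
    """Monte-Carlo background: mean/sd of S for random size-k score sets.

    For each requested size k, ``n_samples`` sets of k scores are sampled
    without replacement from the empirical score pool and their raw scores
    S = Σz/√k summarized.  Implemented with random permutations and prefix
    sums so all sizes share one pass; the per-size marginal distribution is
    exactly that of independent without-replacement draws.
    """
    pool = np.asarray(scores, dtype=float)
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes:
        raise ValidationError("no background sizes requested")
    if n_samples < 100:
        raise ValidationError(f"n_samples must be >= 100, got {n_samples}")
    n = pool.size
    if sizes[0] < 1:
        raise ValidationError("background sizes must be >= 1")
    if sizes[-1] > n:
        raise ValidationError(
            f"background size {sizes[-1]} exceeds number of scored genes ({n})"
        )
    rng = np.random.default_rng(seed)
    kmax = sizes[-1]
    sum_s = {k: 0.0 for k in sizes}
    sum_s2 = {k: 0.0 for k in sizes}
    chunk = max(1, min(n_samples, int(2e6 // max(n, 1)) or 1))
    done = 0
    sqrt_k = {k: math.sqrt(k) for k in sizes}
    while done < n_samples:
        m = min(chunk, n_samples - done)
        # random permutation per row; first k entries are a uniform
        # without-replacement sample of size k
        order = rng.random((m, n)).argsort(axis=1)
        permuted = pool[order]
        csum = permuted.cumsum(axis=1)
        for k in sizes:
            s = csum[:, k - 1] / sqrt_k[k]
            sum_s[k] += float(s.sum())
            sum_s2[k] += float((s * s).sum())
        done += m
    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    for k in sizes:
        mean = sum_s[k] / n_samples
        var = sum_s2[k] / n_samples - mean * mean
        sd = math.sqrt(max(var, 0.0))
        if sd <= 1e-12:
            raise ValidationError(
                f"degenerate background at k={k}: zero score variance "
                "(are all node scores identical, or k equal to the pool size?)"
            )
        means[k] = mean
        sds[k] = sd
    return BackgroundTable(means=means, sds=sds, n_samples=n_samples, seed=seed)


def corrected_score(S: float, k: int, bg: BackgroundTable) -> float:
    """Size-calibrated score (S − mean_k) / sd_k."""
    if k not in bg:
        raise ValidationError(
            f"background table has no entry for size {k}; recalibrate with a "
            "size range covering it"
        )
    return (S - bg.means[k]) / bg.sds[k]


def combine_attributes(calibrated: Sequence[float]) -> float:
    """Combine per-attribute calibrated scores into one module score.

    Scores are sorted descending; for each prefix of j attributes the score
    is ``sum(top j)/sqrt(j)`` minus the expected maximum order statistic of
    j standard normals (selection penalty, shipped constant table).  The
    combined score is the maximum over prefixes; with one attribute it
    reduces to the single calibrated score.
    """
    if not calibrated:
        raise ValidationError("no attribute scores to combine")
    ordered = sorted(calibrated, reverse=True)
    best = -math.inf
    total = 0.0
    for j, s in enumerate(ordered, start=1):
        total += s
        cand = total / math.sqrt(j) - expected_max_order_stat(j)
        best = max(best, cand)
    return best


@dataclass
class _Calibrations:
    """Per-attribute background tables keyed by track name."""

    tables: Mapping[str, BackgroundTable]

    def combined(self, sums: Sequence[float], k: int) -> float:
        sqrt_k = math.sqrt(k)
        cal = [
            corrected_score(sums[i] / sqrt_k, k, self.tables[attr])
            for i, attr in enumerate(TRACKS)
        ]
        return combine_attributes(cal)


def calibrate_all(
    scores: NodeScoreTable,
    max_size: int,
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict[str, BackgroundTable]:
    """Background tables for every attribute, sizes 1..max_size."""
    sizes = range(1, max_size + 1)
    return {
        attr: calibrate_background(
            scores.attribute_array(attr), sizes, n_samples=n_samples, seed=seed + i
        )
        for i, attr in enumerate(TRACKS)
    }


def module_from_genes(
    genes: Iterable[str],
    scores: NodeScoreTable,
    bg: Mapping[str, BackgroundTable],
    seed_gene: str = "",
) -> Module:
    """Score an explicit gene set as a Module (raw/calibrated/combined)."""
    genes = frozenset(genes)
    k = len(genes)
    raw = {}
    cal = {}
    for i, attr in enumerate(TRACKS):
        s = score_subnetwork([scores.z[g][i] for g in genes])
        raw[attr] = s
        cal[attr] = corrected_score(s, k, bg[attr])
    return Module(
        genes=genes,
        raw_scores=raw,
        calibrated_scores=cal,
        combined_score=combine_attributes(list(cal.values())),
        seed_gene=seed_gene or min(genes),
    )


def greedy_search(
    network: PpiNetwork,
    scores: NodeScoreTable,
    bg: Mapping[str, BackgroundTable],
    threshold: float = 3.0,
    max_size: int = 300,
) -> list[Module]:
    """Grow one module from every scored node by strict hill-climbing.

    At each step the frontier neighbor maximizing the combined score is
    added; growth stops as soon as no addition strictly increases the score
    or ``max_size`` is reached.  Ties go to the neighbor with the larger
    total z, then the lexicographically smallest symbol, so results are
    deterministic.  Modules with identical gene sets are merged; only those
    with combined score above ``threshold`` are returned, sorted by score
    descending.
    """
    if len(scores) == 0:
        raise ValidationError("empty node score table")
    cal = _Calibrations(tables=bg)
    zmap = scores.z
    adj = {
        n: sorted(nb for nb in nbs if nb in zmap)
        for n, nbs in network.adjacency().items()
        if n in zmap
    }
    max_size = min(max_size, max(k for k in bg[TRACKS[0]].sizes()))

    best_by_genes: dict[frozenset[str], Module] = {}
    for seed_gene in sorted(zmap):
        if seed_gene not in adj:
            continue
        members = {seed_gene}
        sums = [zmap[seed_gene][0], zmap[seed_gene][1]]
        current = cal.combined(sums, 1)
        frontier = set(adj[seed_gene])
        while len(members) < max_size and frontier:
            best_gain = None
            best_node = None
            for nb in frontier:
                znb = zmap[nb]
                cand = cal.combined(
                    (sums[0] + znb[0], sums[1] + znb[1]), len(members) + 1
                )
                key = (cand, znb[0] + znb[1], _lex_key(nb))
                if best_gain is None or key > best_gain:
                    best_gain = key
                    best_node = nb
            if best_node is None or best_gain[0] <= current:
                break
            members.add(best_node)
            sums[0] += zmap[best_node][0]
            sums[1] += zmap[best_node][1]
            current = best_gain[0]
            frontier.discard(best_node)
            frontier.update(nb for nb in adj[best_node] if nb not in members)
        genes = frozenset(members)
        if genes in best_by_genes:
            continue
        best_by_genes[genes] = module_from_genes(
            genes, scores, bg, seed_gene=seed_gene
        )

    modules = [m for m in best_by_genes.values() if m.combined_score > threshold]
    modules.sort(key=lambda m: (-m.combined_score, sorted(m.genes)))
    logger.info(
        "greedy search: %d distinct module(s), %d above threshold %g",
        len(best_by_genes),
        len(modules),
        threshold,
    )
    return modules


class _lex_key:
    """Orders strings descending so that max() picks the lexicographically
    smallest symbol on full ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_lex_key") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_lex_key") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _lex_key) and self.s == other.s


def overlap_fraction(a: Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / min(|A|, |B|) — overlap on the smaller set."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def select_top_modules(
    modules: Sequence[Module], n: int
) -> tuple[list[Module], dict[tuple[int, int], float]]:
    """Top-n modules by combined score plus pairwise overlap fractions."""
    top = sorted(modules, key=lambda m: (-m.combined_score, sorted(m.genes)))[:n]
    overlaps: dict[tuple[int, int], float] = {}
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            overlaps[(i, j)] = overlap_fraction(top[i].genes, top[j].genes)
    for (i, j), frac in overlaps.items():
        if frac > 0.5:
            logger.info(
                "modules %d and %d overlap extensively (%.0f%%)", i, j, 100 * frac
            )
    return list(top), overlaps
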