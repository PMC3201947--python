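"""Gene-set enrichment of module genes with term grouping.

Each term is tested with a two-sided hypergeometric test (doubling rule),
Bonferroni-corrected over the tested terms.  Redundant terms are grouped by
Cohen's kappa on their gene memberships, each group led by its most
significant term, and the term-level relationships are exported as an
annotation network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from pathgwas.errors import ValidationError
from pathgwas.io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term.

    k_found of the n module genes fall in the K-gene term within the
    N-gene universe; ``percent`` is 100·k_found/K and ``p_corr`` the
    Bonferroni-corrected two-sided hypergeometric p-value.
    """

    term_id: str
    term_name: str
    k_found: int
    K: int
    n: int
    N: int
    p_raw: float
    p_corr: float
    genes_found: tuple[str, ...]

    @property
    def percent(self) -> float:
        return 100.0 * self.k_found / self.K


@dataclass(frozen=True)
class TermGroup:
    """Kappa-linked group of terms with its leading (most significant) term."""

    term_ids: tuple[str, ...]
    leading_term: str


@dataclass(frozen=True)
class AnnotationNode:
    term_id: str
    size: float  # -log10 corrected p
    group_id: int
    leading: bool


@dataclass(frozen=True)
class AnnotationEdge:
    term_a: str
    term_b: str
    kappa: float
    shared_genes: int


@dataclass(frozen=True)
class AnnotationNetwork:
    nodes: tuple[AnnotationNode, ...]
    edges: tuple[AnnotationEdge, ...]


def hypergeom_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided hypergeometric p-value by the doubling rule.

    For X ~ Hypergeometric(N, K, n): p = min(1, 2·min(P(X ≥ k), P(X ≤ k))).
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N and k >= max(0, n + K - N)):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    # unfrozen calls: freezing the distribution dominates runtime when this
    # is evaluated tens of thousands of times (enumeration tests)
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    return min(1.0, 2.0 * min(p_enrich, p_deplete))


def enrich_module(
    module_genes: Iterable[str],
    collection: GeneSetCollection,
    min_genes: int = 3,
) -> list[EnrichmentResult]:
    """Test every term for enrichment of the module genes.

    The universe is the collection's gene union.  Terms with fewer than
    ``min_genes`` module genes are excluded *before* Bonferroni correction.
    Results are sorted by corrected p ascending (ties by term id).
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    universe = collection.universe
    module = set(module_genes) & universe
    n, N = len(module), len(universe)
    if n == 0:
        logger.warning("module is disjoint from the gene-set universe")
        return []
    tested: list[tuple] = []
    for term in collection:
        found = sorted(module & term.genes)
        if len(found) < min_genes:
            continue
        tested.append((term, found))
    m = len(tested)
    results: list[EnrichmentResult] = []
    for term, found in tested:
        K = len(term.genes)
        p_raw = hypergeom_two_sided(len(found), n, K, N)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                k_found=len(found),
                K=K,
                n=n,
                N=N,
                p_raw=p_raw,
                p_corr=min(1.0, p_raw * m),
                genes_found=tuple(found),
            )
        )
    results.sort(key=lambda r: (r.p_corr, r.p_raw, r.term_id))
    logger.info("tested %d term(s) (min_genes=%d), universe %d", m, min_genes, N)
    return results


def kappa(genes_a: Iterable[str], genes_b: Iterable[str], universe: Iterable[str]) -> float:
    """Cohen's kappa between two gene sets' membership vectors over a universe.

    Returns 1.0 for identical sets; symmetric; raises when chance agreement
    is total (both sets equal the universe) but the sets differ — which
    cannot happen — so the only p_e = 1 case returns 1.0.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    a, b = set(genes_a), set(genes_b)
    if not (a <= uni and b <= uni):
        raise ValidationError("gene sets must be subsets of the universe")
    if a == b:
        return 1.0
    N = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    p_o = (n11 + n00) / N
    pa, pb = len(a) / N, len(b) / N
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        raise ValidationError("chance agreement is 1 for differing sets")
    return (p_o - p_e) / (1 - p_e)


def _result_gene_map(results: Sequence[EnrichmentResult]) -> dict[str, frozenset[str]]:
    return {r.term_id: frozenset(r.genes_found) for r in results}


def pairwise_kappa(
    results: Sequence[EnrichmentResult],
    universe: Iterable[str] | None = None,
) -> dict[tuple[str, str], float]:
    """Kappa for every term pair over the union of found genes (or a given
    universe)."""
    gene_map = _result_gene_map(results)
    if universe is None:
        uni: set[str] = set()
        for genes in gene_map.values():
            uni |= genes
    else:
        uni = set(universe)
    out: dict[tuple[str, str], float] = {}
    ids = sorted(gene_map)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1 :]:
            out[(ta, tb)] = kappa(gene_map[ta], gene_map[tb], uni)
    return out


def group_terms(
    results: Sequence[EnrichmentResult],
    kappa_threshold: float = 0.3,
    kappa_matrix: Mapping[tuple[str, str], float] | None = None,
) -> list[TermGroup]:
    """Single-linkage grouping: connected components of the kappa graph.

    Terms are linked when kappa ≥ threshold.  The leading term of a group
    has the smallest corrected p; ties go to the larger k_found, then the
    lexicographically smallest term id.  Output is invariant to the order
    of ``results``.
    """
    if not results:
        raise ValidationError("no enrichment results to group")
    if kappa_matrix is None:
        kappa_matrix = pairwise_kappa(results)
    by_id = {r.term_id: r for r in results}
    parent = {tid: tid for tid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (ta, tb), value in kappa_matrix.items():
        if value >= kappa_threshold:
            ra, rb = find(ta), find(tb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    components: dict[str, list[str]] = {}
    for tid in by_id:
        components.setdefault(find(tid), []).append(tid)

    groups: list[TermGroup] = []
    for members in components.values():
        members.sort()
        lead = min(
            members,
            key=lambda tid: (by_id[tid].p_corr, -by_id[tid].k_found, tid),
        )
        groups.append(TermGroup(term_ids=tuple(members), leading_term=lead))
    groups.sort(key=lambda g: g.term_ids[0])
    return groups


def build_annotation_network(
    results: Sequence[EnrichmentResult],
    groups: Sequence[TermGroup],
    kappa_matrix: Mapping[tuple[str, str], float],
    kappa_threshold: float = 0.3,
) -> AnnotationNetwork:
    """Term-level graph: node size = −log10 corrected p, edges where kappa
    clears the threshold, weighted by kappa and shared-gene count."""
    gene_map = _result_gene_map(results)
    group_of: dict[str, int] = {}
    leading: set[str] = set()
    for gid, group in enumerate(groups, start=1):
        leading.add(group.leading_term)
        for tid in group.term_ids:
            group_of[tid] = gid
    nodes = tuple(
        AnnotationNode(
            term_id=r.term_id,
            size=-math.log10(max(r.p_corr, 1e-300)),
            group_id=group_of.get(r.term_id, 0),
            leading=r.term_id in leading,
        )
        for r in sorted(results, key=lambda r: r.term_id)
    )
    edges = []
    for (ta, tb), value in sorted(kappa_matrix.items()):
        if value >= kappa_threshold:
            edges.append(
                AnnotationEdge(
                    term_a=ta,
                    term_b=tb,
                    kappa=value,
                    shared_genes=len(gene_map[ta] & gene_map[tb]),
                )
            )
    return AnnotationNetwork(nodes=nodes, edges=tuple(edges))


def compare_term_sets(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
) -> dict[str, float]:
    """Per-term proportion k_A/(k_A + k_B) over terms found in either set.

    Equal counts (including a term found in both with the same k) give 0.5.
    """
    ka = {r.term_id: r.k_found for r in results_a}
    kb = {r.term_id: r.k_found for r in results_b}
    out: dict[str, float] = {}
    for tid in sorted(set(ka) | set(kb)):
        a = ka.get(tid, 0)
        b = kb.get(tid, 0)
        out[tid] = 0.5 if a == b else a / (a + b)
    return out


@dataclass(frozen=True)
class DrugTargetOverlap:
    n_targets: int
    gwas_hits: tuple[str, ...]
    pathway_hits: tuple[str, ...]
    gained: tuple[str, ...]  # in pathway union but not the GWAS gene set


def drug_target_overlap(
    gwas_genes: Iterable[str],
    pathway_gene_union: Iterable[str],
    target_list: Iterable[str],
) -> DrugTargetOverlap:
    """Overlap of a drug-target list with GWAS genes vs. pathway-union genes."""
    targets = set(target_list)
    if not targets:
        logger.warning("empty drug-target list")
    gwas = set(gwas_genes)
    union = set(pathway_gene_union)
    gwas_hits = sorted(gwas & targets)
    pathway_hits = sorted(union & targets)
    gained = sorted((union & targets) - gwas)
    return DrugTargetOverlap(
        n_targets=len(targets),
        gwas_hits=tuple(gwas_hits),
        pathway_hits=tuple(pathway_hits),
        gained=tuple(gained),
    )
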