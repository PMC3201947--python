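"""SNP → gene scoring: nominal filtering, prioritization scores, weighted
p-values, gene-wise aggregation and transcription-factor augmentation.

The central quantity is the weighted p-value ``pw = p / 10**ps`` where ``p``
is the association p-value and ``ps`` a non-negative prioritization score
summarizing the SNP's functional evidence; smaller ``pw`` means higher
priority.  Each gene ends up with one weighted p-value per evidence track
("spot" and "fsnp"), taken as the minimum over its assigned SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pathgwas.errors import ConfigurationError, ValidationError
from pathgwas.io_formats import CATEGORY_VOCAB, TRACKS, SnpAnnotationRow, SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrioritizationScheme:
    """Category-weight scheme turning functional evidence into a score.

    ``weights`` maps category codes to non-negative increments, combined by
    ``combine`` ("sum" or "max") and optionally capped at ``cap``.  The
    weights are configuration data, not code: the default below is a
    documented stand-in for external SNP-prioritization services whose
    internal formulas are unpublished.
    """

    weights: Mapping[str, float]
    combine: str = "sum"
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.combine not in ("sum", "max"):
            raise ConfigurationError(f"combine must be sum or max, got {self.combine!r}")
        for cat, w in self.weights.items():
            if w < 0:
                raise ConfigurationError(f"negative weight for category {cat!r}")
        if self.cap is not None and self.cap < 0:
            raise ConfigurationError("cap must be >= 0")


#: Default category weights (documented stand-in; see PrioritizationScheme).
DEFAULT_WEIGHTS: dict[str, float] = {
    "nonsense": 2.0,
    "frameshift": 2.0,
    "missense": 1.5,
    "splicing": 1.5,
    "utr5": 1.0,
    "utr3": 1.0,
    "transcriptional": 1.0,
    "posttranslational": 1.0,
    "conserved": 0.5,
    "intronic": 0.2,
    "ld_proxy": 0.1,
    "intergenic": 0.0,
}

DEFAULT_SCHEME = PrioritizationScheme(weights=DEFAULT_WEIGHTS, combine="sum", cap=3.0)


@dataclass(frozen=True)
class GeneScore:
    """Per-gene pair of weighted p-values with provenance SNPs.

    ``origin`` is ``"gwas-gene"`` for genes reached through SNP assignment
    and ``"tfbs-gene"`` for transcription factors added from TFBS overlap.
    """

    gene: str
    spot_pw: float
    fsnp_pw: float
    spot_snp: str
    fsnp_snp: str
    origin: str = "gwas-gene"

    def __post_init__(self) -> None:
        for name, pw in (("spot_pw", self.spot_pw), ("fsnp_pw", self.fsnp_pw)):
            if not (0.0 < pw <= 1.0):
                raise ValidationError(
                    f"{self.gene}: {name}={pw!r} outside (0, 1]"
                )
        if self.origin not in ("gwas-gene", "tfbs-gene"):
            raise ValidationError(f"unknown origin {self.origin!r}")


def filter_nominal(snps: Sequence[SnpRecord], alpha: float = 0.05) -> list[SnpRecord]:
    """Keep SNPs with p strictly below ``alpha``, preserving order."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    kept = [s for s in snps if s.p < alpha]
    logger.info(
        "nominal filter p < %g: kept %d of %d SNP(s)", alpha, len(kept), len(snps)
    )
    if not kept:
        logger.warning("nominal filter removed every SNP")
    return kept


def compute_ps(row: SnpAnnotationRow, scheme: PrioritizationScheme) -> float:
    """Prioritization score of one annotation row under ``scheme``.

    A ``ps_override`` short-circuits category scoring; otherwise the
    category weights are combined and the cap applied.
    """
    if row.ps_override is not None:
        return row.ps_override
    values = []
    for cat in row.categories:
        if cat not in scheme.weights:
            raise ConfigurationError(
                f"category {cat!r} has no weight in the prioritization scheme"
            )
        values.append(scheme.weights[cat])
    ps = sum(values) if scheme.combine == "sum" else max(values)
    if scheme.cap is not None:
        ps = min(ps, scheme.cap)
    return ps


def weight_pvalue(p: float, ps: float) -> float:
    """Weighted p-value ``p / 10**ps``; always <= p for ps >= 0."""
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p must be in (0, 1], got {p}")
    if ps < 0:
        raise ValidationError(f"prioritization score must be >= 0, got {ps}")
    return p / (10.0**ps)


def assign_snps_to_genes(
    snps: Sequence[SnpRecord],
    annotations: Sequence[SnpAnnotationRow],
    schemes: Mapping[str, PrioritizationScheme] | None = None,
) -> dict[str, dict[str, tuple[str, float]]]:
    """Choose, per SNP and per track, the candidate gene with the highest PS.

    Returns ``{track: {rsid: (gene, ps)}}``.  Ties on PS go to the
    lexicographically smallest gene symbol (logged).  SNPs without any
    annotation row are dropped with a logged count.
    """
    schemes = schemes or {t: DEFAULT_SCHEME for t in TRACKS}
    snp_ids = {s.rsid for s in snps}
    by_track: dict[str, dict[str, list[tuple[str, float]]]] = {t: {} for t in TRACKS}
    for row in annotations:
        if row.rsid not in snp_ids:
            continue
        ps = compute_ps(row, schemes[row.source])
        by_track[row.source].setdefault(row.rsid, []).append((row.gene, ps))

    result: dict[str, dict[str, tuple[str, float]]] = {t: {} for t in TRACKS}
    ties = 0
    for track, per_snp in by_track.items():
        for rsid, candidates in per_snp.items():
            best_ps = max(ps for _, ps in candidates)
            best_genes = sorted(g for g, ps in candidates if ps == best_ps)
            if len(best_genes) > 1:
                ties += 1
            result[track][rsid] = (best_genes[0], best_ps)
    if ties:
        logger.info("broke %d PS tie(s) lexicographically", ties)
    unassigned = len(snp_ids - set().union(*(result[t].keys() for t in TRACKS)))
    if unassigned:
        logger.info("dropped %d SNP(s) without any annotation row", unassigned)
    return result


def aggregate_gene_pw(
    assignments: Mapping[str, Mapping[str, tuple[str, float]]],
    snps: Sequence[SnpRecord],
) -> list[GeneScore]:
    """Aggregate per-SNP weighted p-values to gene-wise minima per track.

    For every gene and track the SNP with the lowest weighted p-value wins
    and its rsID is recorded.  A gene annotated on only one track gets the
    missing attribute from the raw minimum p of its assigned SNPs (PS = 0);
    this fallback is logged.
    """
    p_of = {s.rsid: s.p for s in snps}
    # per track: gene -> (pw, rsid) minimum
    best: dict[str, dict[str, tuple[float, str]]] = {t: {} for t in TRACKS}
    # per gene: raw minimum p over assigned SNPs from any track (PS=0 fallback)
    raw_min: dict[str, tuple[float, str]] = {}
    for track, per_snp in assignments.items():
        for rsid, (gene, ps) in per_snp.items():
            if rsid not in p_of:
                raise ValidationError(f"assigned SNP {rsid!r} has no p-value")
            pw = weight_pvalue(p_of[rsid], ps)
            cur = best[track].get(gene)
            if cur is None or (pw, rsid) < cur:
                best[track][gene] = (pw, rsid)
            raw = raw_min.get(gene)
            if raw is None or (p_of[rsid], rsid) < raw:
                raw_min[gene] = (p_of[rsid], rsid)

    genes = sorted(set(best["spot"]) | set(best["fsnp"]))
    out: list[GeneScore] = []
    fallbacks = 0
    for gene in genes:
        per_attr: dict[str, tuple[float, str]] = {}
        for track in TRACKS:
            if gene in best[track]:
                per_attr[track] = best[track][gene]
            else:
                per_attr[track] = raw_min[gene]
                fallbacks += 1
        out.append(
            GeneScore(
                gene=gene,
                spot_pw=per_attr["spot"][0],
                fsnp_pw=per_attr["fsnp"][0],
                spot_snp=per_attr["spot"][1],
                fsnp_snp=per_attr["fsnp"][1],
                origin="gwas-gene",
            )
        )
    if fallbacks:
        logger.warning(
            "%d gene/track attribute(s) filled from raw minimum p (PS=0 fallback)",
            fallbacks,
        )
    logger.info("aggregated weighted p-values for %d gene(s)", len(out))
    return out


def augment_tfbs(
    gene_scores: Sequence[GeneScore],
    tf_map: Mapping[str, Iterable[str]],
    snps: Sequence[SnpRecord],
    assignments: Mapping[str, Mapping[str, tuple[str, float]]] | None = None,
) -> list[GeneScore]:
    """Add transcription factors whose binding site overlaps a tested SNP.

    For each (SNP, TF) pair where the TF is not already scored, a new
    :class:`GeneScore` is appended carrying the SNP's weighted p-values on
    both tracks (computed with the SNP's assigned PS when available, else
    PS = 0).  TFs already present are left unchanged.  rsIDs in ``tf_map``
    that are not among the filtered SNPs are ignored with a warning.
    """
    p_of = {s.rsid: s.p for s in snps}
    scored = {gs.gene for gs in gene_scores}
    out = list(gene_scores)
    unknown = sorted(set(tf_map) - set(p_of))
    if unknown:
        logger.warning(
            "ignoring %d TF-map rsID(s) not among filtered SNPs", len(unknown)
        )
    added = 0
    for rsid in sorted(set(tf_map) & set(p_of)):
        pw: dict[str, float] = {}
        for track in TRACKS:
            ps = 0.0
            if assignments and rsid in assignments.get(track, {}):
                ps = assignments[track][rsid][1]
            pw[track] = weight_pvalue(p_of[rsid], ps)
        for tf in sorted(set(tf_map[rsid])):
            if tf in scored:
                continue
            out.append(
                GeneScore(
                    gene=tf,
                    spot_pw=pw["spot"],
                    fsnp_pw=pw["fsnp"],
                    spot_snp=rsid,
                    fsnp_snp=rsid,
                    origin="tfbs-gene",
                )
            )
            scored.add(tf)
            added += 1
    if added:
        logger.info("added %d transcription factor(s) from TFBS overlap", added)
    return out


def score_genes(
    snps: Sequence[SnpRecord],
    annotations: Sequence[SnpAnnotationRow],
    tf_map: Mapping[str, Iterable[str]] | None = None,
    alpha: float = 0.05,
    schemes: Mapping[str, PrioritizationScheme] | None = None,
) -> list[GeneScore]:
    """Convenience wrapper chaining filter → assign → aggregate → TF augment."""
    kept = filter_nominal(snps, alpha=alpha)
    assignments = assign_snps_to_genes(kept, annotations, schemes=schemes)
    scores = aggregate_gene_pw(assignments, kept)
    if tf_map:
        scores = augment_tfbs(scores, tf_map, kept, assignments=assignments)
    return scores
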