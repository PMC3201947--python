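"""Synthetic fixture generation with planted ground truth.

Produces a complete, internally consistent set of pipeline inputs — PPI
network, GWAS table, SNP annotations, TF map and gene sets — around a
planted connected module whose genes carry low p-values on both attributes
and a planted term containing most of that module.  Everything is
deterministic under a fixed seed and the ground truth round-trips through
JSON, so parameter-recovery tests need no external data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from pathgwas.errors import ValidationError
from pathgwas.io_formats import (
    GeneSet,
    GeneSetCollection,
    PpiNetwork,
    SnpAnnotationRow,
    SnpRecord,
    write_annotations,
    write_gmt,
    write_gwas_table,
    write_ppi,
    write_tf_map,
)
from pathgwas.snp_scoring import GeneScore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one synthetic fixture (round-trips through JSON)."""

    planted_genes: tuple[str, ...]
    planted_term: str
    signal_strength: float
    attribute_mix: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_genes"] = sorted(self.planted_genes)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["planted_genes"] = tuple(payload["planted_genes"])
        return cls(**payload)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(
    n_nodes: int,
    model: str = "preferential-attachment",
    param: int = 4,
    seed: int = 0,
) -> PpiNetwork:
    """Synthetic PPI: scale-free (preferential attachment) or Erdős–Rényi.

    ``param`` is the attachment count m for preferential attachment and
    the total edge count for the erdos-renyi model.
    """
    import networkx as nx

    if model == "preferential-attachment":
        g = nx.barabasi_albert_graph(n_nodes, param, seed=seed)
    elif model == "erdos-renyi":
        g = nx.gnm_random_graph(n_nodes, param, seed=seed)
    else:
        raise ValidationError(f"unknown network model {model!r}")
    names = {i: _gene_name(i) for i in g.nodes}
    return PpiNetwork.from_edges(
        [(names[a], names[b]) for a, b in g.edges],
        extra_nodes=names.values(),
    )


def _random_walk_module(
    network: PpiNetwork, k_module: int, rng: np.random.Generator
) -> frozenset[str]:
    """Connected k-gene subgraph selected by a seeded random walk."""
    adj = {n: sorted(nb) for n, nb in network.adjacency().items()}
    candidates = sorted(n for n, nb in adj.items() if nb)
    if k_module > len(candidates):
        raise ValidationError(
            f"module size {k_module} exceeds connected node count"
        )
    for _ in range(50):  # restart if the walk gets stuck in a small component
        start = candidates[int(rng.integers(len(candidates)))]
        members = {start}
        current = start
        steps = 0
        while len(members) < k_module and steps < 100 * k_module:
            nbs = adj[current]
            current = nbs[int(rng.integers(len(nbs)))]
            members.add(current)
            steps += 1
        if len(members) == k_module:
            return frozenset(members)
    raise ValidationError("random walk failed to collect a connected module")


def plant_signal(
    network: PpiNetwork,
    k_module: int = 25,
    signal_strength: float = 0.1,
    seed: int = 0,
    attribute_mix: float = 0.3,
) -> tuple[dict[str, tuple[float, float]], SyntheticTruth]:
    """Plant a connected module with low p-values on both attributes.

    Members draw p-values with Beta(signal_strength, 1) marginals through a
    Gaussian copula (correlation ``attribute_mix`` between the two
    attributes); non-members draw independent Uniform(0, 1) per attribute.
    ``signal_strength = 1`` collapses to the null (Beta(1,1) = Uniform).
    """
    if not (0.0 < signal_strength <= 1.0):
        raise ValidationError("signal_strength must be in (0, 1]")
    if not (0.0 <= attribute_mix <= 1.0):
        raise ValidationError("attribute_mix must be in [0, 1]")
    rng = np.random.default_rng([seed, 1])
    members = _random_walk_module(network, k_module, rng)
    pvalues: dict[str, tuple[float, float]] = {}
    rho = attribute_mix
    for gene in sorted(network.nodes):
        if gene in members:
            latent = rng.standard_normal()
            zs = rho * latent + math.sqrt(1 - rho * rho) * rng.standard_normal()
            zf = rho * latent + math.sqrt(1 - rho * rho) * rng.standard_normal()
            us, uf = stats.norm.cdf(zs), stats.norm.cdf(zf)
            # Beta(a, 1) quantile: u ** (1/a)
            ps = float(np.clip(us ** (1.0 / signal_strength), 1e-300, 1.0))
            pf = float(np.clip(uf ** (1.0 / signal_strength), 1e-300, 1.0))
        else:
            draw = rng.random(2)
            ps = float(np.clip(draw[0], 1e-300, 1.0))
            pf = float(np.clip(draw[1], 1e-300, 1.0))
        pvalues[gene] = (ps, pf)
    truth = SyntheticTruth(
        planted_genes=tuple(sorted(members)),
        planted_term="",
        signal_strength=signal_strength,
        attribute_mix=attribute_mix,
        seed=seed,
        params={"k_module": k_module, "n_nodes": network.n_nodes},
    )
    return pvalues, truth


def gene_scores_from_pvalues(
    pvalues: dict[str, tuple[float, float]],
) -> list[GeneScore]:
    """Wrap per-gene attribute p-values as GeneScore records (synthetic rsIDs)."""
    out = []
    for i, gene in enumerate(sorted(pvalues)):
        ps, pf = pvalues[gene]
        out.append(
            GeneScore(
                gene=gene,
                spot_pw=ps,
                fsnp_pw=pf,
                spot_snp=f"rs{i}",
                fsnp_snp=f"rs{i}",
            )
        )
    return out


def generate_gene_sets(
    genes,
    planted_module,
    n_terms: int = 40,
    size_range: tuple[int, int] = (10, 50),
    planted_term_overlap: float = 0.8,
    seed: int = 0,
) -> tuple[GeneSetCollection, str]:
    """Random gene sets plus one designated term covering the planted module.

    Exactly one term (the returned id) contains at least
    ``planted_term_overlap`` of the planted module's genes; the rest are
    uniform random draws within ``size_range``.
    """
    genes = sorted(genes)
    planted = sorted(planted_module)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ValidationError(f"bad size range {size_range} for {len(genes)} genes")
    rng = np.random.default_rng([seed, 2])
    terms: list[GeneSet] = []
    planted_id = "T0000"
    n_core = max(1, math.ceil(planted_term_overlap * len(planted)))
    core = [planted[i] for i in rng.choice(len(planted), size=n_core, replace=False)]
    size = int(rng.integers(max(lo, n_core), hi + 1))
    others = [g for g in genes if g not in set(core)]
    fill_idx = rng.choice(len(others), size=size - n_core, replace=False)
    planted_genes = frozenset(core) | {others[i] for i in fill_idx}
    terms.append(
        GeneSet(term_id=planted_id, term_name="planted pathway", genes=planted_genes)
    )
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        terms.append(
            GeneSet(
                term_id=f"T{t:04d}",
                term_name=f"random pathway {t}",
                genes=frozenset(genes[i] for i in idx),
            )
        )
    return GeneSetCollection(terms=tuple(terms)), planted_id


# small-PS categories safe for decoy SNPs (weights 0 / 0.1 / 0.2)
_DECOY_CATEGORIES = ("intergenic", "ld_proxy", "intronic")


def generate_snp_layer(
    gene_pvalues: dict[str, tuple[float, float]],
    snps_per_gene: int = 3,
    seed: int = 0,
    tf_fraction: float = 0.0,
    n_tf_genes: int = 10,
) -> tuple[list[SnpRecord], list[SnpAnnotationRow], dict[str, set[str]]]:
    """Invert gene scoring: emit SNP tables that reproduce the gene targets.

    Per gene, one *carrier* SNP per attribute track carries exactly the
    gene's intended weighted p-value on that track (p equals the target and
    the category is the zero-weight ``intergenic``, so PS = 0); when both
    targets coincide a single SNP serves both tracks.  Remaining SNPs up to
    ``snps_per_gene`` are decoys with strictly larger weighted p-values
    built from small positive category weights.  A ``tf_fraction`` of
    carrier SNPs additionally maps to synthetic TF gene symbols.

    Run through assignment and aggregation *without* nominal filtering this
    layer reproduces the intended gene table to within 1e-12.
    """
    if snps_per_gene < 1:
        raise ValidationError("snps_per_gene must be >= 1")
    rng = np.random.default_rng([seed, 3])
    records: list[SnpRecord] = []
    rows: list[SnpAnnotationRow] = []
    tf_map: dict[str, set[str]] = {}
    counter = 0
    tf_counter = 0
    carrier_cats = frozenset({"intergenic"})  # weight 0 -> PS = 0 exactly
    for gene in sorted(gene_pvalues):
        t_spot, t_fsnp = gene_pvalues[gene]
        p_min, p_max = min(t_spot, t_fsnp), max(t_spot, t_fsnp)
        min_track = "spot" if t_spot <= t_fsnp else "fsnp"
        n_emitted = 0
        rsid = f"rs{counter:06d}"
        counter += 1
        n_emitted += 1
        records.append(SnpRecord(rsid=rsid, p=p_min))
        rows.append(
            SnpAnnotationRow(
                rsid=rsid, gene=gene, categories=carrier_cats, source=min_track
            )
        )
        if p_max > p_min:
            # second carrier for the other track; its extra row on the
            # min track is a harmless decoy (pw = p_max > p_min)
            rsid2 = f"rs{counter:06d}"
            counter += 1
            n_emitted += 1
            records.append(SnpRecord(rsid=rsid2, p=p_max))
            for track in ("spot", "fsnp"):
                rows.append(
                    SnpAnnotationRow(
                        rsid=rsid2, gene=gene, categories=carrier_cats, source=track
                    )
                )
        else:
            rows.append(
                SnpAnnotationRow(
                    rsid=rsid,
                    gene=gene,
                    categories=carrier_cats,
                    source="fsnp" if min_track == "spot" else "spot",
                )
            )
        if tf_fraction > 0 and rng.random() < tf_fraction:
            tf = f"TF{tf_counter % n_tf_genes:03d}"
            tf_counter += 1
            tf_map.setdefault(rsid, set()).add(tf)
        p_carrier = p_max
        for _ in range(snps_per_gene - n_emitted):
            cat = _DECOY_CATEGORIES[int(rng.integers(len(_DECOY_CATEGORIES)))]
            ps_cat = {"intergenic": 0.0, "ld_proxy": 0.1, "intronic": 0.2}[cat]
            # decoy weighted p must stay above the carrier's targets
            lo = p_carrier
            hi = 10.0 ** (-ps_cat)
            if lo >= hi:
                cat, ps_cat, hi = "intergenic", 0.0, 1.0
            pw_decoy = lo + (hi - lo) * float(rng.random())
            pw_decoy = min(max(pw_decoy, lo), hi)
            p_decoy = min(1.0, pw_decoy * 10.0**ps_cat)
            rsid = f"rs{counter:06d}"
            counter += 1
            records.append(SnpRecord(rsid=rsid, p=p_decoy))
            for track in ("spot", "fsnp"):
                rows.append(
                    SnpAnnotationRow(
                        rsid=rsid,
                        gene=gene,
                        categories=frozenset({cat}),
                        source=track,
                    )
                )
    logger.info(
        "generated %d SNP(s), %d annotation row(s), %d TF link(s)",
        len(records),
        len(rows),
        sum(len(v) for v in tf_map.values()),
    )
    return records, rows, tf_map


def generate_fixture(
    out_dir: str | Path,
    n_nodes: int = 500,
    k_module: int = 25,
    signal_strength: float = 0.1,
    n_terms: int = 40,
    snps_per_gene: int = 3,
    tf_fraction: float = 0.05,
    attribute_mix: float = 0.3,
    model: str = "preferential-attachment",
    model_param: int = 4,
    seed: int = 0,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete synthetic input set plus its truth manifest.

    Files: ppi.tsv (edge list), gwas.tsv, annotations.tsv, tfmap.tsv,
    genesets.gmt, truth.json.  Returns the path map and the truth object.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network = generate_ppi(n_nodes, model=model, param=model_param, seed=seed)
    pvalues, truth = plant_signal(
        network,
        k_module=k_module,
        signal_strength=signal_strength,
        seed=seed,
        attribute_mix=attribute_mix,
    )
    collection, planted_term = generate_gene_sets(
        network.nodes,
        truth.planted_genes,
        n_terms=n_terms,
        seed=seed,
    )
    records, rows, tf_map = generate_snp_layer(
        pvalues,
        snps_per_gene=snps_per_gene,
        seed=seed,
        tf_fraction=tf_fraction,
    )
    truth = SyntheticTruth(
        planted_genes=truth.planted_genes,
        planted_term=planted_term,
        signal_strength=signal_strength,
        attribute_mix=attribute_mix,
        seed=seed,
        params={
            "k_module": k_module,
            "n_nodes": n_nodes,
            "n_terms": n_terms,
            "snps_per_gene": snps_per_gene,
            "tf_fraction": tf_fraction,
            "model": model,
            "model_param": model_param,
        },
    )
    paths = {
        "ppi": out_dir / "ppi.tsv",
        "gwas": out_dir / "gwas.tsv",
        "annotations": out_dir / "annotations.tsv",
        "tf_map": out_dir / "tfmap.tsv",
        "gene_sets": out_dir / "genesets.gmt",
        "truth": out_dir / "truth.json",
    }
    write_ppi(network, paths["ppi"])
    write_gwas_table(records, paths["gwas"])
    write_annotations(rows, paths["annotations"])
    write_tf_map(tf_map, paths["tf_map"])
    write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths, truth
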