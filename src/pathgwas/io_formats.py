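"""Readers/writers for all external file formats plus the domain types.

Every other module consumes the in-memory types defined here; no stage
parses files itself.  Gene identifiers are opaque, case-sensitive strings —
no symbol normalization or aliasing is attempted.

Formats handled: GWAS association tables (TSV/CSV), PPI networks (2-column
edge list or SIF), gene sets (GMT), SNP annotation tables, rsID→TF maps,
plain gene lists, and the TSV run reports.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pathgwas.errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Controlled vocabulary of functional-category codes for SNP annotations.
CATEGORY_VOCAB = frozenset(
    {
        "nonsense",
        "frameshift",
        "missense",
        "utr5",
        "utr3",
        "splicing",
        "transcriptional",
        "posttranslational",
        "conserved",
        "intronic",
        "intergenic",
        "ld_proxy",
    }
)

#: The two scoring tracks a SNP annotation row can feed.
TRACKS = ("spot", "fsnp")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """One tested SNP: identifier plus association p-value in (0, 1]."""

    rsid: str
    p: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("SNP record with empty rsid")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(
                f"p-value for {self.rsid!r} must be in (0, 1], got {self.p!r}"
            )


@dataclass(frozen=True)
class SnpAnnotationRow:
    """One (SNP, candidate gene) annotation feeding one scoring track.

    ``categories`` holds functional-category codes from :data:`CATEGORY_VOCAB`;
    ``ps_override``, when present, is a precomputed prioritization score that
    bypasses category-based scoring entirely.
    """

    rsid: str
    gene: str
    categories: frozenset[str]
    source: str
    ps_override: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid or not self.gene:
            raise ValidationError("annotation row needs both rsid and gene")
        if self.source not in TRACKS:
            raise ValidationError(
                f"annotation track must be one of {TRACKS}, got {self.source!r}"
            )
        if self.ps_override is None and not self.categories:
            raise ValidationError(
                f"annotation row {self.rsid}/{self.gene} has neither "
                "categories nor a ps override"
            )
        if self.ps_override is not None and self.ps_override < 0:
            raise ValidationError(
                f"ps override for {self.rsid}/{self.gene} must be >= 0"
            )


@dataclass(frozen=True)
class PpiNetwork:
    """Undirected simple graph over gene symbols.

    ``edges`` stores unordered pairs as sorted 2-tuples; construction via
    :meth:`from_edges` deduplicates reciprocal edges and drops self-loops.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValidationError(f"edge {(a, b)!r} not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge {(a, b)!r} has endpoint outside nodes")

    @classmethod
    def from_edges(
        cls, pairs: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "PpiNetwork":
        """Build a simple network, dropping self-loops and duplicate edges."""
        edges: set[tuple[str, str]] = set()
        nodes: set[str] = set(extra_nodes)
        dropped = 0
        for a, b in pairs:
            nodes.add(a)
            nodes.add(b)
            if a == b:
                dropped += 1
                continue
            edges.add((a, b) if a < b else (b, a))
        if dropped:
            logger.info("dropped %d self-loop(s)", dropped)
        return cls(nodes=frozenset(nodes), edges=frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self) -> dict[str, int]:
        return {n: len(nb) for n, nb in self.adjacency().items()}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValidationError("gene set with empty term id")
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of gene sets with a derived gene universe."""

    terms: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            if t.term_id in seen:
                raise ValidationError(f"duplicate term id {t.term_id!r}")
            seen.add(t.term_id)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def get(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


# ---------------------------------------------------------------------------
# number formatting (bit-stable TSV output)
# ---------------------------------------------------------------------------


def fmt_float(x: float) -> str:
    """Format a float for TSV output: '.' decimal, scientific below 1e-4."""
    if x != x:  # NaN
        return "nan"
    if x == 0.0:
        return "0"
    if 0.0 < abs(x) < 1e-4:
        return f"{x:.6e}"
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    # tab preferred over comma when both occur
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def _read_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            return [], []
        delim = _sniff_delimiter(first)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        reader = csv.reader(fh, delimiter=delim)
        rows = [row for row in reader if row and any(c.strip() for c in row)]
    return header, rows


def read_gwas_table(
    path: str | Path, p_column: str = "p", id_column: str = "snp"
) -> list[SnpRecord]:
    """Read a SNP association table (rsID + p-value), preserving row order.

    Raises :class:`ConfigurationError` if a named column is missing and
    :class:`ValidationError` (naming the offending row) for non-numeric or
    out-of-range p-values and for duplicate rsIDs.
    """
    header, rows = _read_table(path)
    if not header:
        raise ValidationError(f"{path}: empty GWAS table")
    for col in (id_column, p_column):
        if col not in header:
            raise ConfigurationError(
                f"{path}: column {col!r} not found in header {header}"
            )
    id_idx = header.index(id_column)
    p_idx = header.index(p_column)
    records: list[SnpRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):  # header is line 1
        if max(id_idx, p_idx) >= len(row):
            raise ValidationError(f"{path}: line {i} has too few fields")
        rsid = row[id_idx].strip()
        raw_p = row[p_idx].strip()
        try:
            p = float(raw_p)
        except ValueError:
            raise ValidationError(
                f"{path}: line {i}: non-numeric p-value {raw_p!r}"
            ) from None
        if not (0.0 < p <= 1.0):
            raise ValidationError(
                f"{path}: line {i}: p-value {p} outside (0, 1] for {rsid!r}"
            )
        if rsid in seen:
            raise ValidationError(f"{path}: line {i}: duplicate rsid {rsid!r}")
        seen.add(rsid)
        records.append(SnpRecord(rsid=rsid, p=p))
    logger.info("read %d SNP record(s) from %s", len(records), path)
    return records


def write_gwas_table(
    records: Sequence[SnpRecord],
    path: str | Path,
    p_column: str = "p",
    id_column: str = "snp",
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{id_column}\t{p_column}\n")
        for rec in records:
            fh.write(f"{rec.rsid}\t{rec.p!r}\n")


def read_ppi(path: str | Path, dialect: str = "edge-list") -> PpiNetwork:
    """Read a PPI network from a 2-column edge list or a SIF file.

    SIF lines carry ``source type target [target ...]``; the interaction
    type token is ignored.  Self-loops are dropped (logged) and reciprocal
    or duplicate edges collapsed, so the result is always a simple graph.
    """
    if dialect not in ("edge-list", "sif"):
        raise ConfigurationError(f"unknown PPI dialect {dialect!r}")
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    singletons: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "edge-list":
                if len(fields) < 2:
                    raise ValidationError(
                        f"{path}: line {lineno}: expected two node names"
                    )
                pairs.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) == 1:
                    singletons.append(fields[0])
                elif len(fields) >= 3:
                    src = fields[0]
                    for tgt in fields[2:]:
                        pairs.append((src, tgt))
                else:
                    raise ValidationError(
                        f"{path}: line {lineno}: malformed SIF line"
                    )
    if not pairs and not singletons:
        logger.warning("%s: empty PPI file", path)
    net = PpiNetwork.from_edges(pairs, extra_nodes=singletons)
    logger.info(
        "read PPI network: %d nodes, %d edges from %s",
        net.n_nodes,
        net.n_edges,
        path,
    )
    return net


def write_ppi(network: PpiNetwork, path: str | Path) -> None:
    """Write a network as a sorted 2-column edge list (isolated nodes last)."""
    path = Path(path)
    connected = {n for e in network.edges for n in e}
    with path.open("w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
        for n in sorted(network.nodes - connected):
            fh.write(f"{n}\t{n}\n")  # conventional placeholder, reread as loop


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: term_id, term_name, genes...

    Genes are deduplicated within a term; duplicate term ids and lines with
    fewer than three fields raise :class:`ValidationError`.
    """
    path = Path(path)
    terms: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields"
                )
            term_id, term_name = fields[0], fields[1]
            genes = frozenset(g for g in (f.strip() for f in fields[2:]) if g)
            if term_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate term id {term_id!r}"
                )
            seen.add(term_id)
            terms.append(GeneSet(term_id=term_id, term_name=term_name, genes=genes))
    return GeneSetCollection(terms=tuple(terms))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for t in collection:
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.term_name}\t{genes}\n")


def read_annotations(path: str | Path) -> list[SnpAnnotationRow]:
    """Read the SNP annotation table.

    Columns: rsid, gene, track in {spot, fsnp}, categories (comma-joined
    codes, may be empty when ps is given), ps (optional float).
    """
    header, rows = _read_table(path)
    if not header:
        return []
    required = ("rsid", "gene", "track", "categories")
    for col in required:
        if col not in header:
            raise ConfigurationError(f"{path}: column {col!r} missing")
    idx = {c: header.index(c) for c in header}
    has_ps = "ps" in idx
    out: list[SnpAnnotationRow] = []
    for i, row in enumerate(rows, start=2):
        cats_raw = row[idx["categories"]].strip()
        cats = frozenset(c.strip() for c in cats_raw.split(",") if c.strip())
        unknown = cats - CATEGORY_VOCAB
        if unknown:
            raise ValidationError(
                f"{path}: line {i}: unknown categories {sorted(unknown)}"
            )
        ps: float | None = None
        if has_ps and idx["ps"] < len(row) and row[idx["ps"]].strip():
            try:
                ps = float(row[idx["ps"]])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {i}: non-numeric ps {row[idx['ps']]!r}"
                ) from None
        out.append(
            SnpAnnotationRow(
                rsid=row[idx["rsid"]].strip(),
                gene=row[idx["gene"]].strip(),
                categories=cats,
                source=row[idx["track"]].strip(),
                ps_override=ps,
            )
        )
    return out


def write_annotations(rows: Sequence[SnpAnnotationRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rsid\tgene\ttrack\tcategories\tps\n")
        for r in rows:
            cats = ",".join(sorted(r.categories))
            ps = "" if r.ps_override is None else repr(r.ps_override)
            fh.write(f"{r.rsid}\t{r.gene}\t{r.source}\t{cats}\t{ps}\n")


def read_tf_map(path: str | Path) -> dict[str, set[str]]:
    """Read the rsID → transcription-factor gene table (columns rsid, tf_gene)."""
    header, rows = _read_table(path)
    if not header:
        return {}
    for col in ("rsid", "tf_gene"):
        if col not in header:
            raise ConfigurationError(f"{path}: column {col!r} missing")
    ridx, tidx = header.index("rsid"), header.index("tf_gene")
    out: dict[str, set[str]] = {}
    for row in rows:
        out.setdefault(row[ridx].strip(), set()).add(row[tidx].strip())
    return out


def write_tf_map(tf_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rsid\ttf_gene\n")
        for rsid in sorted(tf_map):
            for tf in sorted(tf_map[rsid]):
                fh.write(f"{rsid}\t{tf}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-gene-per-line list (blank lines and '#' skipped)."""
    path = Path(path)
    genes: list[str] = []
    with path.open() as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


# ---------------------------------------------------------------------------
# run reports
# ---------------------------------------------------------------------------


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a configuration mapping.

    The output directory is excluded so reruns into different directories
    remain byte-identical.
    """
    canon = json.dumps(
        {k: v for k, v in config.items() if k != "out_dir"},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_gene_score_table(gene_scores, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\tspot_pw\tfsnp_pw\tspot_snp\tfsnp_snp\torigin\n")
        for gs in gene_scores:
            fh.write(
                f"{gs.gene}\t{gs.spot_pw!r}\t{gs.fsnp_pw!r}\t"
                f"{gs.spot_snp}\t{gs.fsnp_snp}\t{gs.origin}\n"
            )


def read_gene_score_table(path: str | Path):
    from pathgwas.snp_scoring import GeneScore

    header, rows = _read_table(path)
    expected = ["gene", "spot_pw", "fsnp_pw", "spot_snp", "fsnp_snp", "origin"]
    if header[: len(expected)] != expected:
        raise ValidationError(f"{path}: unexpected gene-score header {header}")
    out = []
    for i, row in enumerate(rows, start=2):
        try:
            out.append(
                GeneScore(
                    gene=row[0],
                    spot_pw=float(row[1]),
                    fsnp_pw=float(row[2]),
                    spot_snp=row[3],
                    fsnp_snp=row[4],
                    origin=row[5],
                )
            )
        except (ValueError, IndexError):
            raise ValidationError(f"{path}: line {i}: malformed row") from None
    return out


def write_module_table(modules, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "module_id\tsize\traw_spot\traw_fsnp\tcal_spot\tcal_fsnp\t"
            "combined\tseed_gene\tgenes\n"
        )
        for i, m in enumerate(modules, start=1):
            genes = ",".join(sorted(m.genes))
            fh.write(
                f"M{i}\t{m.k}\t{fmt_float(m.raw_scores['spot'])}\t"
                f"{fmt_float(m.raw_scores['fsnp'])}\t"
                f"{fmt_float(m.calibrated_scores['spot'])}\t"
                f"{fmt_float(m.calibrated_scores['fsnp'])}\t"
                f"{fmt_float(m.combined_score)}\t{m.seed_gene}\t{genes}\n"
            )


def write_enrichment_table(results, path: str | Path) -> None:
    """Write enrichment results: term, genes found, percent of pathway,
    raw and Bonferroni-corrected p, associated genes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "term_id\tterm_name\tk_found\tpathway_size\tmodule_size\t"
            "universe_size\tpercent\tp_raw\tp_corr\tgenes_found\n"
        )
        for r in results:
            genes = ",".join(r.genes_found)
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k_found}\t{r.K}\t{r.n}\t"
                f"{r.N}\t{fmt_float(r.percent)}\t{fmt_float(r.p_raw)}\t"
                f"{fmt_float(r.p_corr)}\t{genes}\n"
            )


def write_annotation_network_tables(
    annotation_network, nodes_path: str | Path, edges_path: str | Path
) -> None:
    with Path(nodes_path).open("w") as fh:
        fh.write("term_id\tneg_log10_p_corr\tgroup_id\tleading\n")
        for node in annotation_network.nodes:
            fh.write(
                f"{node.term_id}\t{fmt_float(node.size)}\t"
                f"{node.group_id}\t{int(node.leading)}\n"
            )
    with Path(edges_path).open("w") as fh:
        fh.write("term_a\tterm_b\tkappa\tshared_genes\n")
        for edge in annotation_network.edges:
            fh.write(
                f"{edge.term_a}\t{edge.term_b}\t{fmt_float(edge.kappa)}\t"
                f"{edge.shared_genes}\n"
            )


def write_manifest(
    path: str | Path,
    config: Mapping[str, object],
    seed: int | None,
    counts: Mapping[str, object],
    files: Mapping[str, str],
) -> None:
    """Plain-text run manifest: config hash, seed, stage counts, file list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"config_hash\t{config_hash(config)}\n")
        fh.write(f"seed\t{seed}\n")
        for key in sorted(counts):
            fh.write(f"count.{key}\t{counts[key]}\n")
        for key in sorted(files):
            fh.write(f"file.{key}\t{files[key]}\n")


def write_reports(results, out_dir: str | Path) -> dict[str, str]:
    """Write every run report into ``out_dir`` and return the file manifest.

    ``results`` is a :class:`~pathgwas.cli.PipelineResults`-like object with
    attributes ``gene_scores``, ``modules``, ``enrichment``,
    ``annotation_network``, ``config``, ``seed`` and ``counts`` (missing
    pieces are skipped).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    gene_scores = getattr(results, "gene_scores", None)
    if gene_scores is not None:
        p = out_dir / "gene_scores.tsv"
        write_gene_score_table(gene_scores, p)
        files["gene_scores"] = p.name

    modules = getattr(results, "modules", None)
    if modules is not None:
        p = out_dir / "modules.tsv"
        write_module_table(modules, p)
        files["modules"] = p.name

    enrichment = getattr(results, "enrichment", None)
    if enrichment is not None:
        p = out_dir / "enrichment.tsv"
        write_enrichment_table(enrichment, p)
        files["enrichment"] = p.name

    annotation_network = getattr(results, "annotation_network", None)
    if annotation_network is not None:
        np_, ep_ = out_dir / "annotation_nodes.tsv", out_dir / "annotation_edges.tsv"
        write_annotation_network_tables(annotation_network, np_, ep_)
        files["annotation_nodes"] = np_.name
        files["annotation_edges"] = ep_.name

    manifest_path = out_dir / "manifest.txt"
    write_manifest(
        manifest_path,
        getattr(results, "config", {}),
        getattr(results, "seed", None),
        getattr(results, "counts", {}),
        files,
    )
    files["manifest"] = manifest_path.name
    return files
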