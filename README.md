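# pathgwas

Pathway- and network-oriented analysis of GWAS results. Starting from a
table of SNP association p-values, the pipeline:

1. **Scores genes** (`snp_scoring`) — keeps SNPs with nominal evidence
   (p < 0.05 by default), weights each p-value by a functional
   prioritization score (`pw = p / 10**ps`), assigns SNPs to genes by
   highest-priority consequence, aggregates per-gene minima on two evidence
   tracks ("spot" and "fsnp"), and adds transcription factors whose binding
   sites overlap tested SNPs.
2. **Finds active sub-networks** (`subnetwork_search`) — converts gene-wise
   weighted p-values to z-scores, scores connected gene sets with
   `S = sum(z)/sqrt(k)`, standardizes against a Monte-Carlo background of
   10,000 random same-size gene sets, combines the two attributes with a
   rank-penalized maximum, and greedily grows a module from every seed
   node. Modules with combined score > 3 are significant.
3. **Enrichment** (`enrichment`) — two-sided hypergeometric tests of module
   genes against GMT gene sets, Bonferroni correction, Cohen's-kappa term
   grouping with group leading terms, annotation-network export, two-set
   comparison and drug-target overlap reports.
4. **Topology** (`topology`) — degree histograms, log-log power-law fits,
   Erdős–Rényi randomization and Poisson dispersion checks.

`synthetic` generates complete, internally consistent inputs (scale-free
PPI, planted active module, planted enriched term, SNP/annotation/TF
tables that invert step 1 exactly) so everything is testable offline.

## CLI

```sh
# write a synthetic input set with ground truth
pathgwas simulate --n 500 --module-size 25 --terms 40 --seed 7 --out fixture/

# full pipeline: score -> search -> enrich -> topology
pathgwas run-all --gwas fixture/gwas.tsv --annotations fixture/annotations.tsv \
    --tf-map fixture/tfmap.tsv --ppi fixture/ppi.tsv --gmt fixture/genesets.gmt \
    --seed 7 --out results/

# or stage by stage (identical outputs)
pathgwas score  --gwas fixture/gwas.tsv --annotations fixture/annotations.tsv --out scores.tsv
pathgwas search --ppi fixture/ppi.tsv --scores scores.tsv --n-samples 10000 \
    --threshold 3 --max-size 300 --top 5 --seed 7 --out modules.tsv
pathgwas enrich --module modules.tsv --gmt fixture/genesets.gmt --min-genes 3 \
    --kappa 0.3 --out enr
pathgwas topology --ppi fixture/ppi.tsv --out degrees.tsv
```

All parameters can also come from a YAML config (`--config run.yaml`);
explicit flags win. Outputs are plain TSV plus a run manifest carrying a
config hash and the seed; identical inputs and seed reproduce every file
byte for byte.

## Input formats

- **GWAS table** — TSV/CSV with header; columns `snp` and `p` by default.
- **PPI network** — 2-column edge list or SIF; self-loops dropped,
  duplicate/reciprocal edges collapsed.
- **SNP annotations** — TSV with `rsid`, `gene`, `track` (`spot`/`fsnp`),
  `categories` (comma-joined codes such as `missense,conserved`), optional
  `ps` override column.
- **TF map** — TSV with `rsid`, `tf_gene`.
- **Gene sets** — standard GMT.

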