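# lspscan

Detection of whole-genome-duplication (WGD) paralog pairs and
lineage-specific paralog retention (LSP) across a two-lineage species panel,
with a synthetic post-WGD panel generator so the entire cascade is testable
without external data.

## What it does

Given per-species proteomes (FASTA) and gene maps (TSV), plus a panel
definition naming two lineages, their seed genomes and pre-WGD outgroups,
the pipeline:

1. runs all-vs-all Smith–Waterman protein searches (BLOSUM62, affine gaps,
   Karlin–Altschul E-values) or imports externally computed 12-column
   tabular hit files;
2. calls candidate duplicate pairs in each seed genome from mutual
   above-cutoff self-hits (default E ≤ 1e-80), excluding larger families;
3. filters isoform/chimera-like pairs (coverage and length-ratio rules) and
   same-chromosome pairs;
4. requires a unique singleton ortholog in every outgroup genome;
5. scores copy number (0 / 1 / 2+, different chromosomes required for 2+)
   in every other panel species via reciprocal hit support;
6. classifies each family: `A_LSP` (duplicate throughout lineage A, single
   copy throughout lineage B), `B_LSP`, `shared_duplicate`, or `unresolved`;
7. verifies LSP calls with a neighbor-joining duplication-topology test
   (Poisson-corrected distances, outgroup rooting) and a neighborhood-overlap
   synteny score;
8. reports per-chromosome retention ratios (pseudoreplicate mean ± SE),
   Spearman correlation with a permutation p-value, and hypergeometric
   GO-slim enrichment with Benjamini–Hochberg control.

The `synthetic_panel` module simulates a panel descended from a common
ancestor through one WGD with lineage-stem and per-species paralog losses,
chromosome placement and peptide divergence, emitting ground-truth retention
labels (`truth.tsv`) for every family.

## CLI

```sh
# simulate a synthetic panel (writes per-species FASTA + gene maps + truth.tsv)
lspscan simulate --config sim.yaml --out-dir panel/

# one-shot: full cascade + verification + statistics
lspscan run-all --config panel/panel.yaml --panel-dir panel/ --out-dir results/

# individual stages
lspscan search --config panel/panel.yaml --panel-dir panel/ --from spA1 --to spB1 --out hits.tsv
lspscan call-tsgd     --config panel/panel.yaml --panel-dir panel/ --out-dir results/
lspscan classify-lsp  --config panel/panel.yaml --panel-dir panel/ --out-dir results/
lspscan verify        --config panel/panel.yaml --panel-dir panel/ --out-dir results/
lspscan stats         --config panel/panel.yaml --panel-dir panel/ --out-dir results/
lspscan enrich --study study_genes.txt --annotation ann.tsv --slim slim.tsv --out enrichment.tsv
```

A minimal simulation config (`sim.yaml`):

```yaml
n_families: 500
peptide_length: 200
wgd_retention_prob: 0.6
loss_prob_a: 0.25
loss_prob_b: 0.25
per_species_loss_prob: 0.0
divergence_pre_split: 0.03
divergence_post_split: 0.02
seed: 1
species_panel:
  lineage_a: [spA1, spA2]
  lineage_b: [spB1, spB2]
  outgroups: [og1]
  seed_a: spA1
  seed_b: spB1
  seed: 1
```

Results are plain TSVs (`tsgd_pairs.tsv`, `lsp_calls.tsv`,
`chromosome_stats.tsv`, `enrichment.tsv`, `verification.tsv`, `drops.tsv`),
newick trees (`trees.nwk`) and a JSON summary with headline counts and
percentages. Re-running with the same config and seed reproduces
byte-identical outputs.

## Module layout

| module | contents |
| --- | --- |
| `lspscan.io_formats` | `Gene`/`PanelConfig` types, FASTA + gene-map readers/writers, 12-column hit-table I/O, annotation/slim tables |
| `lspscan.synthetic_panel` | `SimConfig`, `simulate_panel`, `mutate_peptide`, truth-table I/O |
| `lspscan.homology_search` | Smith–Waterman alignment, bitscores/E-values, `all_vs_all`, reciprocal best hits |
| `lspscan.paralog_pipeline` | duplicate-pair calling, artifact exclusion, outgroup singleton test, copy number, LSP classification, panel summary |
| `lspscan.verification` | Poisson-corrected distances, neighbor joining, duplication-topology test, synteny scores |
| `lspscan.retention_stats` | chromosome pseudoreplicate statistics, Spearman + permutation p, hypergeometric enrichment, BH adjustment, slim mapping |
| `lspscan.pipeline` | `run_pipeline` orchestration and result writers |
| `lspscan.cli` | `lspscan` command-line entry point |
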