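# cislnc

Cell-type-resolved analysis of long noncoding RNAs (lncRNAs) in single-cell
and spatial transcriptomics of developing tissue.

During development, many lncRNAs sit next to protein-coding genes in the
genome and are co-expressed with them inside specific cell populations —
candidate *cis*-regulatory pairs. `cislnc` provides the computational
machinery to find and describe them, for researchers who already have a
clustered count matrix and a genome annotation:

* **QC + normalization** — cell filters (UMI < 8000, mito < 10%,
  500 ≤ detected genes ≤ 4000), log-normalization
  `x = ln(1 + 10⁴·n/N)`, cell-cycle module scores with binned control sets,
  and removal of cycling cells (highest phase score ≥ 0.3).
* **Marker statistics** — one-vs-rest Wilcoxon rank-sum tests per cluster
  (exact tie-aware enumeration at small n), Benjamini-Hochberg adjustment,
  top-N marker lists, and Mann-Whitney comparisons of lncRNA vs
  protein-coding expression distributions.
* **Positional classification** — every lncRNA is assigned one of six
  strand-aware categories relative to coding gene models (intergenic,
  bidirectional, intronic, antisense, sense, overlapping) with its nearest
  partner and signed distance.
* **cis/trans pairing** — a (lncRNA, coding gene, cluster) record is a *cis*
  pair when the genes lie ≤100 kb apart and the within-cluster Pearson
  |r| > 0.95 on normalized values; *trans* pairs are distant coding genes
  with |r| > 0.45.
* **Spatial co-expression** — binarized per-bin expression maps merged into
  both/only_a/only_b/neither states, summarized by anatomical domain
  (central canal, ventral, dorsal, marginal), with per-stage expression
  trends and cluster-profile correlations (flagged at r ≥ 0.7, p < 0.05).
* **Synthetic data** — a seeded generator producing a toy genome (GTF),
  cluster-structured negative-binomial counts (MTX + sidecars) and a labeled
  spatial grid with known ground truth, so the whole pipeline is testable
  without external data.

## Worked example

Run the full pipeline on the default synthetic dataset (10 clusters × 200
cells, 1000 coding genes, 60 lncRNAs, 20 planted cis pairs):

```sh
cislnc all -o demo --seed 1
```

```
report written to demo/report.json
cells kept 1752/2000; cis pairs 20, trans pairs 0
```

`demo/report.json` then contains (excerpt):

```json
"qc":       {"cells_in": 2000, "cells_out": 1752, "failed_umi": 3,
             "failed_mito": 245, "failed_genes": 0, "non_cycling": 1455},
"category_counts": {"intergenic": 10, "bidirectional": 10, "intronic": 10,
                    "antisense": 10, "sense": 10, "overlapping": 10},
"pairs":    {"cis_total": 20, "trans_total": 0,
             "per_cluster_percent": {"C00": 10.0, "...": "..."}}
```

Reading: 248 of 2000 cells fail the QC gates (3 by the UMI cap, 245 by the
mitochondrial cap), and 297 of the survivors are flagged as cycling and
dropped. The classifier recovers the generator's 10 lncRNAs in each of the
six positional categories, and pair calling finds exactly the 20 planted cis
pairs — 2 per cluster, hence 10.0% each — with no false calls and no trans
calls (the generator plants no trans structure). Per-stage outputs
(`markers.tsv`, `lncrna_classes.tsv`, `pairs.tsv`, `domain_summary.json`,
`stage_trends.tsv`, `cluster_correlation.tsv`) land next to the report, and
`cislnc validate -o demo` re-checks their invariants.

Each stage is also callable as a library function (`cislnc.qc.filter_cells`,
`cislnc.position.classify_all`, `cislnc.pairs.call_pairs`, ...) on
`AnnData`/`GenomeAnnotation` objects, and as individual subcommands
(`simulate`, `qc`, `markers`, `classify`, `pairs`, `spatial`) so real data
can replace any stage's input.

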