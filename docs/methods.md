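# Methods

`cislnc` re-implements, as a tested and reusable pipeline, the lncRNA-centric
computational workflow of a developmental single-cell + spatial
transcriptomics study: cell-level QC and normalization, cell-cycle gating,
cluster marker statistics, strand-aware positional classification of lncRNAs,
cluster-wise cis/trans co-expression pairing, and binarized spatial
co-expression mapping. All stages run on data from the bundled synthetic
generator, whose ground truth makes every stage verifiable.

## QC and normalization

Cells are kept when total UMIs < 8,000 (strict: a total of exactly 8,000 is
excluded), mitochondrial fraction < 0.10, and the number of detected genes
(raw count > 0) lies in [500, 4000]. The mitochondrial fraction is taken from
the `mito_frac` metadata column when present, otherwise computed from
transcript ids with a configurable prefix (default `MT-`). Normalization is
the global-scaling log transform

    x_ct = ln(1 + s * n_ct / N_c),   s = 10,000 (default)

with `n_ct` the raw count of transcript `t` in cell `c` and `N_c` the cell
total; a zero-total cell is an error naming the cell.

## Cell-cycle module scores

For each named phase gene set `G` the module score of a cell is
`mean(x over G) − mean(x over C)`, where the control set `C` is assembled by
cutting all transcripts into `n_bins` (default 24) bins of average
expression and drawing up to `n_ctrl` (default 100) controls, without
replacement, from the bin of each phase gene (seeded RNG; a bin smaller than
`n_ctrl` contributes all of its members, so an exhaustive single-bin
configuration makes the score exactly zero when the phase set is the whole
transcriptome). Any number of named phase sets is supported; a cell is
non-cycling when its highest phase score is below the cutoff (default 0.3).
The control-set construction is the standard binned-background module score;
the binning and sampling parameters are explicit config so scores are exactly
reproducible.

## Marker statistics

Markers are one-vs-rest per cluster. The test is the two-sided Wilcoxon
rank-sum on normalized values: for groups of at most 25 cells each, the exact
permutation distribution of the rank sum is computed with a subset-sum
dynamic program over (doubled, tie-aware) midranks and the two-sided p
doubles the smaller tail (capped at 1); for larger groups the normal
approximation with tie correction and a 0.5 continuity correction is used.
P-values are Benjamini-Hochberg adjusted within each cluster's transcript
family, and a marker is significant at adjusted p < 0.05. Clusters with fewer
than 3 cells are skipped with a record.

`top_transcripts` returns, by default, the de-duplicated union of significant
cluster markers ordered by (best adjusted p, higher in-cluster mean, id) and
truncated to n = 2,000 — the marker-union reading of a "top 2,000" list. A
config switch (`expression` mode) instead ranks all transcripts by overall
mean normalized expression; both readings are implemented because the source
workflow is ambiguous between them.

Biotype comparisons reduce each transcript to two summaries — median
normalized expression over cells, and percent of cells expressing — and
compare lncRNA vs protein-coding groups with the two-sided Mann-Whitney U
test (scipy).

## Positional classification

Gene models are 0-based half-open internally; GTF input/output is 1-based
closed, and genes without exon features receive one implicit exon spanning
the gene. Every lncRNA receives exactly one of six categories by first-match
precedence:

1. **intronic** — span fully inside a single intron of some coding
   transcript, either strand;
2. **antisense** — ≥1 bp of exon-exon overlap with a coding gene on the
   opposite strand;
3. **sense** — ≥1 bp of exon-exon overlap on the same strand, and the lncRNA
   does not contain the whole coding gene;
4. **overlapping** — span overlap without exonic overlap, or full containment
   of a coding gene;
5. **bidirectional** — no overlap, and the lncRNA TSS lies within
   `bidirectional_window` (default 1 kb, configurable; the source work states
   no number) of a coding TSS in divergent head-to-head orientation;
6. **intergenic** — everything else, with the nearest coding gene within
   100 kb recorded as a partner when one exists.

The explicit precedence makes the partition property testable; ties between
equidistant partners break lexicographically by gene id. Distances are
measured between gene spans (closest ends; overlap = 0) except bidirectional,
which reports the TSS-to-TSS gap; signs are relative to the partner's
orientation (downstream positive). Overlap always means a non-empty half-open
intersection. The category vocabulary in the source work is internally
inconsistent ("five classes", a six-item list, "seven groups"); this
implementation fixes the six listed categories.

## cis/trans co-expression pairs

Candidate cis partners of a lncRNA are coding genes on the same chromosome
within 100 kb of its span (inclusive; overlap = distance 0). For each cluster
with at least `min_cells` (default 10) cells, the Pearson correlation of the
two transcripts' normalized values over that cluster's cells is computed
cell-level (not on cluster-mean profiles); a cis pair is called per
(lncRNA, gene, cluster) when |r| > 0.95, strictly. Trans pairs are coding
genes outside the window (or on another chromosome) with |r| > 0.45,
restricted to a caller-supplied universe (the pipeline uses the top-marker
list) to bound cost. A pair passing in k clusters yields k records; distinct
pair and member counts are reported separately. Summaries print per-cluster
(and optional per-lineage) counts with percentages rounded half-up to one
decimal. The source work prints two cis totals (307/279) and two trans
thresholds (0.45/0.4); defaults follow its methods section (0.95/0.45) and
the thresholds used are echoed into the summary metadata. Coding partners are
not required to be cluster markers before pairing.

## Spatial co-expression

Bins are abstract grid units with user-supplied coordinates, a stage label
and one of four anatomical domains (central_canal, ventral, dorsal,
marginal); domain geometry is an input labeling, not inferred from images.
Binarization is count > 0 by default (the simplest defensible reading of
color-coded expression dots, which the source work does not threshold
explicitly), with a depth-robust quantile mode (count above the q-th quantile
of the transcript's nonzero bins). Two binarized maps merge into per-bin
states both/only_a/only_b/neither; domain summaries report each domain's
both-fraction and its ratio to the all-bin fraction (empty domains report
undefined, not 0). Stage trends label a transcript increasing/decreasing only
when per-stage means are strictly monotone in stage order; ties are
non-monotone to avoid over-claiming. Cluster spatial correlation flags
cluster mean-profile pairs with Pearson r ≥ 0.7 and t-distribution p < 0.05.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
verified. Defaults: 10 clusters × 200 cells over stages GW8/GW10/GW12
(assigned round-robin so every stage is populated), 1,000 coding genes and 10
lncRNAs per positional category on one synthetic chromosome `chrS1`, 20
planted cis pairs at target r 0.99, a 10% cycling subpopulation, negative
binomial counts with dispersion 0.1 at mean depth 3,000, and a 12×12 spatial
grid per stage. 1,000 coding genes keep detected-gene counts (~600-950 per
cell) inside the 500-4,000 QC gate so the default pipeline is
self-consistent.

Coding genes carry 3 exons (first intron ≥1.5 kb) and never overlap; each
non-intergenic lncRNA is constructed around a distinct coding anchor so that
it satisfies exactly one category's definition, and intergenic lncRNAs live
in a reserved region >100 kb from all coding genes. The classifier
round-trips the construction exactly (tested over 20 seeds).

Counts are Gamma-Poisson around per-cluster mean profiles rescaled to the
target depth; each cluster has 25 planted markers at 5-fold elevation, and
cycling cells over-express the bundled S/G2M sets 4-fold (cell counts round
half-up). Planted cis-pair members are re-sampled inside their target cluster
as Poisson draws around a shared mean-one lognormal per-cell factor — an NB
mixture that keeps counts integral and overdispersed without copying values.
The factor's log-variance `s` is solved self-consistently from
`s = r/(1−r) · (e^s/m + τ₀)` (with `m` the pair's mean count and τ₀ = 0.004
residual noise); because counting noise grows as `e^s/m`, very high targets
are unattainable at realistic means, and the generator then uses the variance
that empirically maximizes the realized correlation (s = 0.8, realized
r ≈ 0.96-0.98 at target 0.99, with ≥90% of pairs above |r| = 0.95). The
spatial grid fixes domains geometrically (outer ring marginal, small central
block central_canal, upper/lower interior dorsal/ventral) and elevates 5
domain markers 6-fold only inside their domain, plus the first planted pair
in ventral bins.

What the generator does **not** emulate: read-level structure, UMI
collisions, ambient RNA, doublets, batch effects, realistic gene-length or
GC covariates, trans-regulatory structure (trans calling is verified on
constructed fixtures), and any spatial autocorrelation beyond the domain
blocks. Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under a clean NB world, not robustness to the
artifacts of real libraries.

## Numerical choices

Natural logs throughout; sparse matrices preserved where practical. The exact
rank-sum DP switches to the normal approximation above 25 cells per side.
Pearson r uses a commutative dot-product formulation so r(a,b) and r(b,a) are
bit-identical; zero-variance columns are skipped with a recorded reason, not
NaN-propagated. Percentages round half-up (`decimal`), never banker's
rounding. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; the generator derives independent streams per
stage from `SeedSequence([seed, stream])`, so outputs are byte-identical
across runs with the same config. The pipeline's `report.json` carries a
config hash (outdir excluded) and the seed.

## Known limitations

Single-chromosome defaults (multi-chromosome annotations are supported by the
data model but not generated); no promoter/enhancer/CTCF track integration;
no clustering, embedding, trajectory, deconvolution or enrichment analysis —
cluster labels, stages and domains are inputs by design. Published headline
counts that depend on the study's deposited raw data (cell totals, the
381/2,000 lncRNA share, the exact category split and pair totals) are not
desk-scale reproducible and are treated as reporting-arithmetic checks only.
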