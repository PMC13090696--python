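"""Synthetic genome, single-cell and spatial data with known ground truth.

The generator emulates the statistical shape of a developmental single-cell +
spatial transcriptomics study so that every downstream stage of the pipeline
can be exercised against a known answer:

* a single synthetic chromosome (``chrS1``) carrying non-overlapping
  protein-coding gene models (3 exons each) and lncRNAs constructed to satisfy
  exactly one of the six positional categories;
* cluster-structured negative-binomial counts over three gestational stages,
  with planted cluster markers, a cycling-cell subpopulation over-expressing
  bundled S/G2M gene sets, and planted cis pairs whose members share a
  per-cell latent factor inside one target cluster;
* a rectangular spatial grid partitioned into four anatomical domains
  (central canal, ventral, dorsal, marginal) with domain-restricted marker
  transcripts and one ventral-planted co-expression pair.

All outputs are pure functions of the configuration: the same seed yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from cislnc._stats import round_half_up
from cislnc.position import GeneModel, GenomeAnnotation

CHROM = "chrS1"

#: pre-normalization mean of a planted cis-pair member in its target cluster,
#: in the same arbitrary units as the lognormal base means (~1); high enough
#: that Poisson noise does not dominate the shared latent factor.
PAIR_MEAN = 80.0

#: residual log-scale noise not explained by counting error (depth
#: normalization, log1p curvature at low counts)
PAIR_TAU2_EXTRA = 0.004

#: latent log-variance used when the requested correlation exceeds what the
#: noise floor allows; near the argmax of realized r over the latent variance
PAIR_LATENT_VAR_MAXED = 0.8

MARKERS_PER_CLUSTER = 25
MARKER_FOLD = 5.0
CYCLING_FOLD = 4.0
DOMAIN_FOLD = 6.0
DOMAINS = ("central_canal", "ventral", "dorsal", "marginal")


class GenerationError(RuntimeError):
    """Raised when the requested annotation cannot be constructed."""


class PlantedPair(NamedTuple):
    lncrna_id: str
    gene_id: str
    cluster: str
    target_r: float


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic data.

    Defaults describe a mid-sized desk-scale study: 10 clusters of 200 cells
    across three gestational stages, ~1000 coding genes, 10 lncRNAs per
    positional category, 20 planted cis pairs at target within-cluster
    Pearson r of 0.99, a 10% cycling subpopulation, and a 12x12 spatial grid
    per stage.
    """

    seed: int = 0
    n_clusters: int = 10
    cells_per_cluster: int = 200
    n_coding_genes: int = 1000
    n_lncrna_per_category: int = 10
    n_planted_cis_pairs: int = 20
    target_cis_r: float = 0.99
    cycling_fraction: float = 0.1
    stages: tuple[str, ...] = ("GW8", "GW10", "GW12")
    grid_shape: tuple[int, int] = (12, 12)
    nb_dispersion: float = 0.1
    mean_depth: int = 3000

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cells_per_cluster < 0:
            raise ValueError("cells_per_cluster must be >= 0")
        if self.n_coding_genes < 1:
            raise ValueError("n_coding_genes must be >= 1")
        if self.n_lncrna_per_category < 0:
            raise ValueError("n_lncrna_per_category must be >= 0")
        if not 0.0 < self.target_cis_r < 1.0:
            raise ValueError("target_cis_r must lie strictly between 0 and 1")
        if not 0.0 <= self.cycling_fraction <= 1.0:
            raise ValueError("cycling_fraction must lie in [0, 1]")
        if not self.stages:
            raise ValueError("at least one stage label is required")
        if self.grid_shape[0] < 4 or self.grid_shape[1] < 4:
            raise ValueError("grid_shape must be at least (4, 4)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def cluster_labels(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_clusters)]

    def stage_of_cluster(self, i: int) -> str:
        # round-robin so every stage is populated
        return self.stages[i % len(self.stages)]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline is asked to recover."""

    lncrna_category: dict[str, str] = field(default_factory=dict)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    cycling_cells: set[str] = field(default_factory=set)
    domain_of_bin: dict[str, str] = field(default_factory=dict)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    phase_sets: dict[str, list[str]] = field(default_factory=dict)
    domain_markers: dict[str, list[str]] = field(default_factory=dict)
    ventral_pair: tuple[str, str] | None = None

    def to_dict(self) -> dict:
        return {
            "lncrna_category": self.lncrna_category,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "cycling_cells": sorted(self.cycling_cells),
            "domain_of_bin": self.domain_of_bin,
            "marker_genes": self.marker_genes,
            "phase_sets": self.phase_sets,
            "domain_markers": self.domain_markers,
            "ventral_pair": list(self.ventral_pair) if self.ventral_pair else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            lncrna_category=d["lncrna_category"],
            planted_pairs=[PlantedPair(*p) for p in d["planted_pairs"]],
            cycling_cells=set(d["cycling_cells"]),
            domain_of_bin=d["domain_of_bin"],
            marker_genes=d.get("marker_genes", {}),
            phase_sets=d.get("phase_sets", {}),
            domain_markers=d.get("domain_markers", {}),
            ventral_pair=tuple(d["ventral_pair"]) if d.get("ventral_pair") else None,
        )


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _make_coding_gene(rng: np.random.Generator, gid: str, start: int) -> GeneModel:
    a = int(rng.integers(300, 800))
    i1 = int(rng.integers(1500, 2500))
    b = int(rng.integers(300, 800))
    i2 = int(rng.integers(500, 1000))
    c = int(rng.integers(300, 800))
    strand = "+" if rng.random() < 0.5 else "-"
    e1 = (start, start + a)
    e2 = (e1[1] + i1, e1[1] + i1 + b)
    e3 = (e2[1] + i2, e2[1] + i2 + c)
    return GeneModel(gid, CHROM, start, e3[1], strand, "protein_coding", {f"{gid}.t1": [e1, e2, e3]})


def _single_exon_lnc(lid: str, start: int, end: int, strand: str) -> GeneModel:
    return GeneModel(lid, CHROM, start, end, strand, "lncRNA", {f"{lid}.t1": [(start, end)]})


def make_genome(cfg: SyntheticConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build the synthetic annotation and its positional-category ground truth.

    Each non-intergenic lncRNA is constructed around a distinct coding
    "anchor" gene; intergenic lncRNAs live in a reserved region more than
    100 kb away from every coding gene. Planted cis pairs are drawn from the
    anchored lncRNAs (all within 100 kb of their anchor) and assigned a target
    cluster round-robin via the seeded RNG.
    """
    cfg.validate()
    rng = _rng(cfg, 0)

    genes: list[GeneModel] = []
    pos = 10_000
    for i in range(cfg.n_coding_genes):
        g = _make_coding_gene(rng, f"PCG{i:04d}", pos)
        genes.append(g)
        pos = g.end + int(rng.integers(8000, 20000))

    truth = GroundTruth()
    n_cat = cfg.n_lncrna_per_category
    anchored_categories = ("intronic", "antisense", "sense", "overlapping", "bidirectional")
    if n_cat > 0 and len(anchored_categories) * n_cat > cfg.n_coding_genes:
        raise GenerationError(
            f"need {len(anchored_categories) * n_cat} anchor genes for the anchored "
            f"categories but only {cfg.n_coding_genes} coding genes are configured"
        )

    lnc_models: list[GeneModel] = []
    anchor_of: dict[str, str] = {}
    if n_cat > 0:
        anchor_idx = rng.choice(cfg.n_coding_genes, size=len(anchored_categories) * n_cat, replace=False)
        for c_i, category in enumerate(anchored_categories):
            for j in range(n_cat):
                g = genes[int(anchor_idx[c_i * n_cat + j])]
                lid = f"LNC_{category.upper()[:4]}_{j:03d}"
                exons = g.transcripts[f"{g.gene_id}.t1"]
                if category == "intronic":
                    i1s, i1e = exons[0][1], exons[1][0]
                    if i1e - i1s < 300:
                        raise GenerationError("could not place intronic lncRNA: intron too short")
                    strand = "+" if rng.random() < 0.5 else "-"
                    lnc = _single_exon_lnc(lid, i1s + 100, i1e - 100, strand)
                elif category in ("antisense", "sense"):
                    ov = min(200, exons[0][1] - exons[0][0])
                    d = int(rng.integers(300, 900))
                    strand = ("-" if g.strand == "+" else "+") if category == "antisense" else g.strand
                    lnc = _single_exon_lnc(lid, g.start - d, g.start + ov, strand)
                elif category == "overlapping":
                    lnc = _single_exon_lnc(lid, g.start - 300, g.end + 300, g.strand)
                else:  # bidirectional: divergent promoter within 1 kb of the anchor TSS
                    gap = int(rng.integers(200, 800))
                    length = int(rng.integers(400, 900))
                    if g.strand == "+":
                        lnc = _single_exon_lnc(lid, g.start - gap - length, g.start - gap, "-")
                    else:
                        lnc = _single_exon_lnc(lid, g.end + gap, g.end + gap + length, "+")
                lnc_models.append(lnc)
                truth.lncrna_category[lid] = category
                anchor_of[lid] = g.gene_id

        # intergenic: reserved region >100 kb beyond the last coding gene
        ipos = pos + 150_000
        for j in range(n_cat):
            length = int(rng.integers(500, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
            lid = f"LNC_INTE_{j:03d}"
            lnc_models.append(_single_exon_lnc(lid, ipos, ipos + length, strand))
            truth.lncrna_category[lid] = "intergenic"
            ipos += length + int(rng.integers(2000, 5000))

    ann = GenomeAnnotation(genes + lnc_models)

    # planted cis pairs among the anchored lncRNAs (all are <=100 kb candidates)
    candidates = sorted(anchor_of)
    if cfg.n_planted_cis_pairs > len(candidates):
        raise GenerationError(
            f"requested {cfg.n_planted_cis_pairs} planted cis pairs but only "
            f"{len(candidates)} anchored lncRNA candidates exist"
        )
    if cfg.n_planted_cis_pairs > 0:
        chosen = rng.choice(len(candidates), size=cfg.n_planted_cis_pairs, replace=False)
        labels = cfg.cluster_labels()
        for k, idx in enumerate(sorted(int(i) for i in chosen)):
            lid = candidates[idx]
            truth.planted_pairs.append(
                PlantedPair(lid, anchor_of[lid], labels[k % len(labels)], cfg.target_cis_r)
            )
    return ann, truth


# ---------------------------------------------------------------------------
# single-cell expression
# ---------------------------------------------------------------------------


def _latent_log_variance(target_r: float, mean_count: float) -> float:
    """Log-scale variance of the shared per-cell factor for a planted pair.

    On log-normalized values the pair's correlation is roughly
    ``r = s / (s + tau2(s))`` where ``s`` is the shared latent variance and
    ``tau2(s) = exp(s)/m + extra`` the independent counting noise (the
    ``exp(s)`` term is E[1/f] under a mean-one lognormal factor). The fixed
    point of ``s = r/(1-r) * tau2(s)`` is found by iteration; when the target
    is unattainable at the given mean count the tangency point
    ``s = ln(m * (1-r)/r)``, which maximizes the achievable correlation, is
    used instead.
    """
    ratio = target_r / (1.0 - target_r)
    s = ratio * (1.0 / mean_count + PAIR_TAU2_EXTRA)
    cap = np.log(max(mean_count / ratio, 1.05))
    for _ in range(100):
        nxt = ratio * (np.exp(s) / mean_count + PAIR_TAU2_EXTRA)
        if nxt > cap:
            # target unattainable at this mean: use the variance that
            # empirically maximizes the realized correlation
            return max(cap, PAIR_LATENT_VAR_MAXED)
        if abs(nxt - s) < 1e-10:
            return nxt
        s = nxt
    return min(s, cap)


def _gene_order(ann: GenomeAnnotation) -> list[str]:
    return [g.gene_id for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))]


def make_expression(ann: GenomeAnnotation, truth: GroundTruth, cfg: SyntheticConfig) -> ad.AnnData:
    """Simulate cluster-structured NB counts; fills ``truth`` with markers,
    phase sets and cycling cells.

    Counts are Gamma-Poisson (negative binomial) around per-cluster mean
    profiles scaled to ``mean_depth`` per cell. Planted cis-pair members are
    re-sampled inside their target cluster as Poisson draws around a shared
    lognormal per-cell factor, which induces the target within-cluster
    correlation on log-normalized values while keeping counts integral and
    overdispersed.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    gene_ids = _gene_order(ann)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    labels = cfg.cluster_labels()

    pair_members = {p.lncrna_id for p in truth.planted_pairs} | {p.gene_id for p in truth.planted_pairs}
    coding_ids = [g.gene_id for g in ann.coding_genes()]
    reserved = set(pair_members)

    # bundled cell-cycle phase sets (coding genes, disjoint from pair members)
    free = [g for g in coding_ids if g not in reserved]
    n_s, n_g2m = min(20, len(free) // 4), min(30, len(free) // 4)
    phase_pick = rng.choice(len(free), size=n_s + n_g2m, replace=False)
    truth.phase_sets = {
        "S": sorted(free[int(i)] for i in phase_pick[:n_s]),
        "G2M": sorted(free[int(i)] for i in phase_pick[n_s:]),
    }
    reserved |= {g for s in truth.phase_sets.values() for g in s}

    # planted cluster markers: >=20 per cluster with elevated mean
    pool = [g for g in coding_ids if g not in reserved]
    per = MARKERS_PER_CLUSTER
    truth.marker_genes = {}
    if len(pool) >= per * cfg.n_clusters:
        pick = rng.choice(len(pool), size=per * cfg.n_clusters, replace=False)
        for i, lab in enumerate(labels):
            truth.marker_genes[lab] = sorted(pool[int(j)] for j in pick[i * per : (i + 1) * per])
    else:
        for lab in labels:
            pick = rng.choice(len(pool), size=min(per, len(pool)), replace=False)
            truth.marker_genes[lab] = sorted(pool[int(j)] for j in pick)

    # per-cluster mean profiles
    base = rng.lognormal(mean=0.0, sigma=0.8, size=n_genes)
    mean_mat = np.tile(base, (cfg.n_clusters, 1))
    for i, lab in enumerate(labels):
        for g in truth.marker_genes[lab]:
            mean_mat[i, gene_pos[g]] *= MARKER_FOLD
    for p in truth.planted_pairs:
        if p.cluster not in labels:
            continue
        k = labels.index(p.cluster)
        mean_mat[k, gene_pos[p.lncrna_id]] = PAIR_MEAN
        mean_mat[k, gene_pos[p.gene_id]] = PAIR_MEAN
    mean_mat *= cfg.mean_depth / mean_mat.sum(axis=1, keepdims=True)

    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    obs = pd.DataFrame(
        {
            "cluster": np.repeat(labels, cfg.cells_per_cluster),
            "stage": np.repeat(
                [cfg.stage_of_cluster(i) for i in range(cfg.n_clusters)], cfg.cells_per_cluster
            ),
            "mito_frac": rng.beta(2.5, 40.0, size=n_cells),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame({"biotype": [ann[g].biotype for g in gene_ids]}, index=gene_ids)

    if n_cells == 0:
        return ad.AnnData(X=sparse.csr_matrix((0, n_genes), dtype=np.int32), obs=obs, var=var)

    depth = rng.lognormal(mean=-0.02, sigma=0.2, size=n_cells)
    rate = mean_mat[np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)] * depth[:, None]

    # cycling subpopulation over-expresses the S/G2M sets (rounding half-up)
    n_cyc = int(round_half_up(cfg.cycling_fraction * n_cells, 0))
    cyc_idx = np.sort(rng.choice(n_cells, size=n_cyc, replace=False)) if n_cyc else np.array([], dtype=int)
    truth.cycling_cells = {obs.index[int(i)] for i in cyc_idx}
    phase_cols = [gene_pos[g] for s in truth.phase_sets.values() for g in s]
    if len(cyc_idx) and phase_cols:
        rate[np.ix_(cyc_idx, phase_cols)] *= CYCLING_FOLD

    alpha = cfg.nb_dispersion
    counts = rng.poisson(rng.gamma(shape=1.0 / alpha, scale=alpha * rate)).astype(np.int32)

    # correlated re-sampling of pair members inside their target cluster
    cluster_arr = obs["cluster"].to_numpy()
    for p in truth.planted_pairs:
        cells = np.flatnonzero(cluster_arr == p.cluster)
        if len(cells) == 0:
            continue
        il, ig = gene_pos[p.lncrna_id], gene_pos[p.gene_id]
        m_l, m_g = rate[cells, il], rate[cells, ig]
        sigma2 = _latent_log_variance(p.target_r, 2.0 / (1.0 / m_l.mean() + 1.0 / m_g.mean()))
        f = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(cells)))
        counts[cells, il] = rng.poisson(m_l * f)
        counts[cells, ig] = rng.poisson(m_g * f)

    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)


# ---------------------------------------------------------------------------
# spatial grid
# ---------------------------------------------------------------------------


def domain_layout(rows: int, cols: int) -> dict[tuple[int, int], str]:
    """Fixed geometric domain labeling of a rows x cols grid.

    The outermost ring is ``marginal``; a small central block is
    ``central_canal``; the remaining upper half is ``dorsal`` and the lower
    half ``ventral``.
    """
    if rows < 4 or cols < 4:
        raise ValueError("grid must be at least 4x4")
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    out = {}
    for r in range(rows):
        for c in range(cols):
            if r in (0, rows - 1) or c in (0, cols - 1):
                out[(r, c)] = "marginal"
            elif abs(r - cr) <= rows / 8.0 and abs(c - cc) <= cols / 8.0:
                out[(r, c)] = "central_canal"
            elif r < cr:
                out[(r, c)] = "dorsal"
            else:
                out[(r, c)] = "ventral"
    return out


def make_spatial(ann: GenomeAnnotation, truth: GroundTruth, cfg: SyntheticConfig) -> ad.AnnData:
    """Simulate bin x transcript counts on one grid per stage.

    Domain-marker transcripts (5 coding genes per domain, plus the first
    planted cis pair in the ventral domain) have their means inflated only in
    their domain's bins. Fills ``truth.domain_of_bin``,
    ``truth.domain_markers`` and ``truth.ventral_pair``.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    rows, cols = cfg.grid_shape
    layout = domain_layout(rows, cols)
    gene_ids = _gene_order(ann)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    coding_ids = [g.gene_id for g in ann.coding_genes()]

    pair_members = {p.lncrna_id for p in truth.planted_pairs} | {p.gene_id for p in truth.planted_pairs}
    pool = [g for g in coding_ids if g not in pair_members]
    n_mark = min(5, max(1, len(pool) // len(DOMAINS)))
    pick = rng.choice(len(pool), size=n_mark * len(DOMAINS), replace=False)
    truth.domain_markers = {
        d: sorted(pool[int(j)] for j in pick[i * n_mark : (i + 1) * n_mark]) for i, d in enumerate(DOMAINS)
    }
    if truth.planted_pairs:
        p = truth.planted_pairs[0]
        truth.ventral_pair = (p.lncrna_id, p.gene_id)

    records = []
    for stage in cfg.stages:
        for r in range(rows):
            for c in range(cols):
                records.append((f"{stage}_bin_{r:02d}_{c:02d}", c, r, layout[(r, c)], stage))
    obs = pd.DataFrame(records, columns=["bin_id", "x", "y", "domain", "stage"]).set_index(
        "bin_id", drop=False
    )
    obs.index.name = None
    truth.domain_of_bin = dict(zip(obs["bin_id"], obs["domain"]))

    base = rng.lognormal(mean=0.0, sigma=0.8, size=len(gene_ids))
    base *= cfg.mean_depth / base.sum()
    rate = np.tile(base, (len(obs), 1))
    domain_arr = obs["domain"].to_numpy()
    for d, markers in truth.domain_markers.items():
        idx = np.flatnonzero(domain_arr == d)
        cols_idx = [gene_pos[g] for g in markers]
        rate[np.ix_(idx, cols_idx)] *= DOMAIN_FOLD
    if truth.ventral_pair:
        idx = np.flatnonzero(domain_arr == "ventral")
        cols_idx = [gene_pos[g] for g in truth.ventral_pair]
        rate[np.ix_(idx, cols_idx)] *= DOMAIN_FOLD

    alpha = cfg.nb_dispersion
    counts = rng.poisson(rng.gamma(shape=1.0 / alpha, scale=alpha * rate)).astype(np.int32)
    var = pd.DataFrame({"biotype": [ann[g].biotype for g in gene_ids]}, index=gene_ids)
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs.drop(columns=["bin_id"]), var=var)
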