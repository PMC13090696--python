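"""End-to-end orchestration: simulate -> qc -> markers -> classify -> pairs -> spatial.

Every stage reads and writes plain-text artifacts in the run directory so any
stage's input can be replaced with real data. ``report.json`` aggregates the
headline numbers (QC gate counts, non-cycling cells, marker counts, lncRNA
share of the top-N list, positional category counts, cis/trans totals,
per-cluster pair percentages, domain co-expression summaries) and stamps the
config hash and seed. ``validate_outputs`` re-checks the type invariants over
the emitted files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from cislnc import io as cio
from cislnc import markers as cmarkers
from cislnc import pairs as cpairs
from cislnc import qc as cqc
from cislnc import spatial as cspatial
from cislnc.position import CATEGORIES, classify_all, load_annotation, write_gtf
from cislnc.synthetic import GroundTruth, SyntheticConfig, make_expression, make_genome, make_spatial

SCHEMA_VERSION = "1.0"

log = logging.getLogger("cislnc")


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters plus input paths; serializes losslessly to YAML."""

    outdir: str = "cislnc_run"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = dataclasses.field(default_factory=dict)
    # explicit inputs, used when simulate is false
    annotation: str | None = None
    cells_dir: str | None = None
    phase_sets: str | None = None
    spatial_dir: str | None = None
    # QC gates
    max_umi: int = 8000
    max_mito: float = 0.10
    min_genes: int = 500
    max_genes: int = 4000
    scale_factor: float = 10_000.0
    # cell-cycle scoring
    cycle_n_bins: int = 24
    cycle_n_ctrl: int = 100
    cycle_cutoff: float = 0.3
    # markers
    top_n: int = 2000
    top_mode: str = "marker_union"
    # classifier
    bidirectional_window: int = 1000
    # pairing
    cis_window: int = 100_000
    cis_r: float = 0.95
    trans_r: float = 0.45
    min_cells: int = 10
    # spatial
    binarize_mode: str = "positive"
    binarize_q: float = 0.75
    n_map_pairs: int = 1
    spatial_threshold_r: float = 0.7
    spatial_alpha: float = 0.05
    lineage_map: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.trans_r > self.cis_r:
            raise ValueError("trans_r must not exceed cis_r")
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must lie in [0, 1]")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if self.top_n <= 0:
            raise ValueError("top_n must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def synthetic_config(self) -> SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        return SyntheticConfig(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc
            log.info("[%s] done", name)
            return out

        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, outdir: Path):
    scfg = cfg.synthetic_config()
    ann, truth = make_genome(scfg)
    cells = make_expression(ann, truth, scfg)
    bins = make_spatial(ann, truth, scfg)
    syn = outdir / "synthetic"
    syn.mkdir(parents=True, exist_ok=True)
    write_gtf(ann, syn / "annotation.gtf")
    cio.write_mtx_bundle(cells, syn / "cells")
    cio.write_mtx_bundle(bins, syn / "spatial", meta_name="spatial_bins.tsv")
    cio.write_phase_sets(truth.phase_sets, syn / "phase_sets.tsv")
    cio.write_json(truth.to_dict(), syn / "ground_truth.json")
    return ann, cells, bins, truth


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate:
        syn = outdir / "synthetic"
        ann = load_annotation(syn / "annotation.gtf")
        cells = cio.read_mtx_bundle(syn / "cells")
        bins = cio.read_mtx_bundle(syn / "spatial", meta_name="spatial_bins.tsv")
        phase_sets = cio.read_phase_sets(syn / "phase_sets.tsv")
    else:
        ann = load_annotation(cfg.annotation)
        cells = cio.read_mtx_bundle(cfg.cells_dir)
        bins = cio.read_mtx_bundle(cfg.spatial_dir, meta_name="spatial_bins.tsv") if cfg.spatial_dir else None
        phase_sets = cio.read_phase_sets(cfg.phase_sets)
    return ann, cells, bins, phase_sets


@_stage("qc")
def stage_qc(cfg: PipelineConfig, outdir: Path, cells, phase_sets):
    thr = cqc.QcThresholds(cfg.max_umi, cfg.max_mito, cfg.min_genes, cfg.max_genes)
    filtered, report = cqc.filter_cells(cells, thr)
    if filtered.n_obs == 0:
        log.warning("[qc] all cells removed by the QC gates")
    cio.write_mtx_bundle(filtered, outdir / "filtered")
    norm = cqc.lognormalize(filtered, cfg.scale_factor)
    scores = cqc.score_cell_cycle(
        norm, phase_sets, n_bins=cfg.cycle_n_bins, n_ctrl=cfg.cycle_n_ctrl,
        seed=cfg.seed, cutoff=cfg.cycle_cutoff,
    )
    scores.to_csv(outdir / "cell_cycle_scores.tsv", sep="\t", index_label="cell_id")
    noncycling = cqc.drop_cycling(scores, norm, cfg.cycle_cutoff)
    report["non_cycling"] = int(noncycling.n_obs)
    report["cycling_removed"] = int(norm.n_obs - noncycling.n_obs)
    cio.write_json(report, outdir / "qc_report.json")
    return noncycling, report


@_stage("markers")
def stage_markers(cfg: PipelineConfig, outdir: Path, norm):
    results = cmarkers.find_markers(norm)
    df = cmarkers.markers_frame(results)
    df.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    top = cmarkers.top_transcripts(results, n=cfg.top_n, mode=cfg.top_mode, norm=norm)
    pd.Series(top, name="transcript_id").to_csv(outdir / "top_transcripts.tsv", sep="\t", index=False)
    bio = cmarkers.biotype_comparison(norm)
    cio.write_json(bio, outdir / "biotype_comparison.json")
    return results, top, bio


@_stage("classify")
def stage_classify(cfg: PipelineConfig, outdir: Path, ann):
    calls, table = classify_all(ann, cfg.bidirectional_window)
    rows = [
        {
            "lncrna_id": c.lncrna_id,
            "category": c.category,
            "partner_gene_id": c.partner_gene_id if c.partner_gene_id else "",
            "signed_distance": c.signed_distance,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["lncrna_id", "category", "partner_gene_id", "signed_distance"]).to_csv(
        outdir / "lncrna_classes.tsv", sep="\t", index=False
    )
    cio.write_json(table, outdir / "category_counts.json")
    return calls, table


@_stage("pairs")
def stage_pairs(cfg: PipelineConfig, outdir: Path, ann, norm, top, calls):
    pairs = cpairs.call_pairs(
        ann, norm, cis_window=cfg.cis_window, cis_r=cfg.cis_r, trans_r=cfg.trans_r,
        min_cells=cfg.min_cells, trans_universe=top,
    )
    df = cpairs.pairs_frame(pairs)
    category_of = {c.lncrna_id: c.category for c in calls}
    if len(df):
        df["lncrna_category"] = df["lncrna_id"].map(category_of)
    else:
        df["lncrna_category"] = pd.Series(dtype=str)
    df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    summary = {
        "cis": cpairs.summarize_pairs(df, cfg.lineage_map, mode="cis"),
        "trans": cpairs.summarize_pairs(df, cfg.lineage_map, mode="trans"),
        "thresholds": {"cis_window": cfg.cis_window, "cis_r": cfg.cis_r, "trans_r": cfg.trans_r},
    }
    cio.write_json(summary, outdir / "pair_summary.json")
    return df, summary


@_stage("spatial")
def stage_spatial(cfg: PipelineConfig, outdir: Path, bins, norm, pairs_df):
    results = {"maps": {}}
    cis = pairs_df[pairs_df["mode"] == "cis"] if len(pairs_df) else pairs_df
    chosen = []
    if len(cis):
        ranked = cis.reindex(cis["pearson_r"].abs().sort_values(ascending=False).index)
        seen = set()
        for _, row in ranked.iterrows():
            key = (row["lncrna_id"], row["gene_id"])
            if key not in seen and row["lncrna_id"] in bins.var_names and row["gene_id"] in bins.var_names:
                seen.add(key)
                chosen.append(key)
            if len(chosen) >= cfg.n_map_pairs:
                break
    domain_summaries = {}
    trends = []
    for a, b in chosen:
        cmap = cspatial.merge_pair(bins, a, b, mode=cfg.binarize_mode, q=cfg.binarize_q)
        cmap.states.rename("state").to_csv(
            outdir / f"coexpression_map_{a}_{b}.tsv", sep="\t", index_label="bin_id"
        )
        domain_summaries[f"{a}|{b}"] = cspatial.domain_summary(cmap, bins)
        results["maps"][f"{a}|{b}"] = cmap.state_counts()
        for t in (a, b):
            tr = cspatial.stage_trend(norm, t)
            trends.append({"transcript_id": t, "direction": tr.direction, **tr.stage_means})
    cio.write_json(domain_summaries, outdir / "domain_summary.json")
    trend_df = pd.DataFrame(trends).drop_duplicates(subset="transcript_id") if trends else pd.DataFrame(
        columns=["transcript_id", "direction"]
    )
    trend_df.to_csv(outdir / "stage_trends.tsv", sep="\t", index=False)
    profiles = cspatial.cluster_profiles(norm)
    corr = cspatial.cluster_spatial_correlation(profiles, cfg.spatial_threshold_r, cfg.spatial_alpha)
    corr.to_csv(outdir / "cluster_correlation.tsv", sep="\t", index=False)
    results["domain_summaries"] = domain_summaries
    results["cluster_correlation_flagged"] = int(corr["flagged"].sum())
    return results


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and write ``report.json``; returns the report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        stage_simulate(cfg, outdir)
    # read through the exchange formats so the pipeline exercises them
    ann, cells, bins, phase_sets = _load_inputs(cfg, outdir)

    norm, qc_report = stage_qc(cfg, outdir, cells, phase_sets)
    results, top, bio = stage_markers(cfg, outdir, norm)
    calls, table = stage_classify(cfg, outdir, ann)
    pairs_df, pair_summary = stage_pairs(cfg, outdir, ann, norm, top, calls)
    spatial_results = stage_spatial(cfg, outdir, bins, norm, pairs_df) if bins is not None else {}

    lnc_ids = {g.gene_id for g in ann.lncrnas()}
    top_lnc = sum(1 for t in top if t in lnc_ids)
    marker_counts = (
        cmarkers.markers_frame(results)
        .query("adjusted_p < 0.05")
        .groupby("cluster")
        .size()
        .to_dict()
    )
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "qc": qc_report,
        "markers": {"significant_per_cluster": {k: int(v) for k, v in sorted(marker_counts.items())}},
        "top_transcripts": {
            "n": len(top),
            "lncrna_count": top_lnc,
            "lncrna_share": round(top_lnc / len(top), 4) if top else None,
        },
        "category_counts": table,
        "pairs": {
            "cis_total": pair_summary["cis"]["total_pairs"],
            "trans_total": pair_summary["trans"]["total_pairs"],
            "per_cluster_percent": {
                k: v["percent"] for k, v in pair_summary["cis"]["per_cluster"].items()
            },
        },
        "spatial": spatial_results,
        "biotype_comparison": bio,
    }
    cio.write_json(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# output validation
# ---------------------------------------------------------------------------


def validate_outputs(outdir) -> tuple[bool, list[str]]:
    """Re-check type invariants over an emitted run directory.

    Returns (passed, violations). Missing files are violations, not crashes.
    """
    outdir = Path(outdir)
    violations: list[str] = []

    def need(name: str) -> Path | None:
        p = outdir / name
        if not p.exists():
            violations.append(f"missing file: {name}")
            return None
        return p

    report_p = need("report.json")
    report = cio.read_json(report_p) if report_p else {}

    classes_p = need("lncrna_classes.tsv")
    counts_p = need("category_counts.json")
    if classes_p and counts_p:
        classes = pd.read_csv(classes_p, sep="\t")
        counts = cio.read_json(counts_p)
        bad = set(classes["category"]) - set(CATEGORIES)
        if bad:
            violations.append(f"lncrna_classes.tsv: unknown categories {sorted(bad)}")
        if classes["lncrna_id"].duplicated().any():
            violations.append("lncrna_classes.tsv: duplicated lncrna ids")
        if sum(counts.values()) != len(classes):
            violations.append(
                f"category partition violated: counts sum {sum(counts.values())} != {len(classes)} lncRNAs"
            )
        for cat, n in classes["category"].value_counts().items():
            if counts.get(cat, 0) != n:
                violations.append(f"category_counts.json mismatch for {cat}: {counts.get(cat)} != {n}")
        overlap_cats = {"intronic", "antisense", "sense", "overlapping"}
        bad_dist = classes[
            (classes["category"].isin(overlap_cats)) & (classes["signed_distance"] != 0)
        ]
        if len(bad_dist):
            violations.append(
                f"nonzero distance on overlap-category rows: {bad_dist['lncrna_id'].tolist()[:5]}"
            )

    pairs_p = need("pairs.tsv")
    if pairs_p:
        pairs = pd.read_csv(pairs_p, sep="\t")
        thr = (cio.read_json(outdir / "pair_summary.json").get("thresholds", {})
               if (outdir / "pair_summary.json").exists() else {})
        cis_window = thr.get("cis_window", 100_000)
        cis_r = thr.get("cis_r", 0.95)
        trans_r = thr.get("trans_r", 0.45)
        for i, row in pairs.iterrows():
            if row["mode"] == "cis":
                if not (pd.notna(row["genomic_distance"]) and row["genomic_distance"] <= cis_window):
                    violations.append(f"pairs.tsv row {i}: cis pair beyond window")
                if abs(row["pearson_r"]) <= cis_r:
                    violations.append(f"pairs.tsv row {i}: cis |r| not above {cis_r}")
            elif row["mode"] == "trans":
                if abs(row["pearson_r"]) <= trans_r:
                    violations.append(f"pairs.tsv row {i}: trans |r| not above {trans_r}")
            else:
                violations.append(f"pairs.tsv row {i}: unknown mode {row['mode']!r}")
        if report:
            cis = pairs[pairs["mode"] == "cis"]
            expected = {
                k: cpairs.summarize_pairs(pairs, mode="cis")["per_cluster"][k]["percent"]
                for k in cis["cluster"].astype(str).unique()
            } if len(cis) else {}
            got = report.get("pairs", {}).get("per_cluster_percent", {})
            if {str(k): v for k, v in got.items()} != {str(k): v for k, v in expected.items()}:
                violations.append("report.json per-cluster pair percentages do not recompute from pairs.tsv")

    bins_p = outdir / "synthetic" / "spatial" / "spatial_bins.tsv"
    if bins_p.exists():
        bins_meta = pd.read_csv(bins_p, sep="\t")
        for map_file in sorted(outdir.glob("coexpression_map_*.tsv")):
            states = pd.read_csv(map_file, sep="\t")
            if len(states) != len(bins_meta):
                violations.append(f"{map_file.name}: state rows {len(states)} != bins {len(bins_meta)}")
            bad = set(states["state"]) - set(cspatial.STATES)
            if bad:
                violations.append(f"{map_file.name}: unknown states {sorted(bad)}")

    qc_p = need("qc_report.json")
    if qc_p:
        qc = cio.read_json(qc_p)
        if qc.get("cells_out", 0) > qc.get("cells_in", 0):
            violations.append("qc_report.json: more cells out than in")

    return (not violations), violations


def setup_logging(verbosity: int) -> None:
    level = logging.WARNING if verbosity < 0 else logging.INFO if verbosity == 0 else logging.DEBUG
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")
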