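"""Cluster-wise cis/trans lncRNA-coding-gene co-expression pairing.

A lncRNA and a protein-coding gene form a *cis* pair when they lie within
``cis_window`` (default 100 kb, inclusive; overlap counts as distance 0) on
the same chromosome and their log-normalized expression over one cluster's
cells has |Pearson r| strictly above ``cis_r`` (default 0.95). *Trans* pairs
are coding genes outside the cis window (or on another chromosome) with
|r| strictly above ``trans_r`` (default 0.45), restricted to a caller-supplied
transcript universe to bound cost. Correlation is always computed cell-level
within a cluster; clusters below ``min_cells`` or with a zero-variance member
are skipped with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from cislnc._stats import round_half_up
from cislnc.position import GenomeAnnotation

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_CIS_R = 0.95
DEFAULT_TRANS_R = 0.45
DEFAULT_MIN_CELLS = 10


@dataclass(frozen=True)
class CoexpressionPair:
    lncrna_id: str
    gene_id: str
    cluster: str
    mode: str  # cis | trans
    pearson_r: float
    genomic_distance: int | None  # bp between spans; None for trans
    n_cells: int


def _span_distance(a, b) -> int:
    if a.chrom != b.chrom:
        raise ValueError("span distance is undefined across chromosomes")
    if a.start >= b.end:
        return a.start - b.end
    if b.start >= a.end:
        return b.start - a.end
    return 0


def candidate_cis_partners(
    ann: GenomeAnnotation, lncrna_id: str, window: int = DEFAULT_CIS_WINDOW
) -> list[tuple[str, int]]:
    """Protein-coding genes within ``window`` bp (inclusive) of the lncRNA span,
    as (gene_id, distance) sorted by distance then gene_id."""
    lnc = ann[lncrna_id]
    out = []
    for g in ann.coding_near(lnc.chrom, lnc.start, lnc.end, pad=window + 1):
        d = _span_distance(lnc, g)
        if d <= window:
            out.append((g.gene_id, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


def _dense_column(norm: ad.AnnData, transcript: str) -> np.ndarray:
    if transcript not in norm.var_names:
        raise KeyError(f"transcript {transcript!r} not in matrix")
    j = norm.var_names.get_loc(transcript)
    col = norm.X[:, j]
    return np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()


def pearson_by_cluster(
    norm: ad.AnnData,
    a: str,
    b: str,
    cluster_key: str = "cluster",
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[dict[str, float], dict[str, str]]:
    """Per-cluster Pearson r of two transcripts; returns (r by cluster, skip reasons)."""
    va, vb = _dense_column(norm, a), _dense_column(norm, b)
    clusters = norm.obs[cluster_key].astype(str).to_numpy()
    rs: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for lab in sorted(set(clusters)):
        mask = clusters == lab
        if mask.sum() < min_cells:
            skipped[lab] = f"fewer than {min_cells} cells"
            continue
        xa, xb = va[mask], vb[mask]
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            skipped[lab] = "zero variance"
            continue
        # commutative formulation: identical bits for (a, b) and (b, a)
        cov = np.dot(xa - xa.mean(), xb - xb.mean()) / len(xa)
        rs[lab] = float(cov / (sa * sb))
    return rs, skipped


def _cluster_correlations(x: np.ndarray) -> np.ndarray:
    """Column-standardize and return the full correlation matrix; zero-variance
    columns yield NaN rows/cols."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = np.nan
    return (z.T @ z) / x.shape[0]


def call_pairs(
    ann: GenomeAnnotation,
    norm: ad.AnnData,
    cluster_key: str = "cluster",
    cis_window: int = DEFAULT_CIS_WINDOW,
    cis_r: float = DEFAULT_CIS_R,
    trans_r: float = DEFAULT_TRANS_R,
    min_cells: int = DEFAULT_MIN_CELLS,
    trans_universe: list[str] | None = None,
) -> list[CoexpressionPair]:
    """Call all cis and trans pairs, one record per (lncRNA, gene, cluster).

    Thresholds are strict (``|r| > cis_r``, ``|r| > trans_r``). Trans pairing
    is restricted to coding genes in ``trans_universe`` (skipped entirely when
    None). A pair passing in k clusters yields k records.
    """
    if trans_r > cis_r:
        raise ValueError("trans_r must not exceed cis_r")
    x = norm.X.toarray() if sparse.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    names = list(norm.var_names)
    pos = {n: i for i, n in enumerate(names)}
    clusters = norm.obs[cluster_key].astype(str).to_numpy()
    lncs = [g for g in ann.lncrnas() if g.gene_id in pos]
    coding = {g.gene_id: g for g in ann.coding_genes()}

    universe = [t for t in (trans_universe or []) if t in pos and t in coding]
    lncs = sorted(lncs, key=lambda g: g.gene_id)

    # genomic candidates are cluster-independent: compute them once
    cis_cands = {lnc.gene_id: candidate_cis_partners(ann, lnc.gene_id, cis_window) for lnc in lncs}
    trans_targets: dict[str, list[str]] = {}
    for lnc in lncs:
        excluded = {gid for gid, _ in cis_cands[lnc.gene_id]}
        trans_targets[lnc.gene_id] = [
            gid
            for gid in universe
            if gid not in excluded
            and (coding[gid].chrom != lnc.chrom or _span_distance(lnc, coding[gid]) > cis_window)
        ]

    pairs: list[CoexpressionPair] = []
    uni_idx = np.array([pos[g] for g in universe], dtype=int)
    for lab in sorted(set(clusters)):
        mask = clusters == lab
        n1 = int(mask.sum())
        if n1 < min_cells:
            continue
        sub = x[mask]
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (sub - mu) / sd

        for lnc in lncs:
            il = pos[lnc.gene_id]
            if sd[il] == 0:
                continue
            for gid, dist in cis_cands[lnc.gene_id]:
                if gid not in pos or sd[pos[gid]] == 0:
                    continue
                r = float(z[:, il] @ z[:, pos[gid]] / n1)
                if abs(r) > cis_r:
                    pairs.append(CoexpressionPair(lnc.gene_id, gid, lab, "cis", r, dist, n1))
        if len(uni_idx):
            lnc_ok = [lnc for lnc in lncs if sd[pos[lnc.gene_id]] > 0]
            if lnc_ok:
                lidx = np.array([pos[lnc.gene_id] for lnc in lnc_ok], dtype=int)
                rmat = z[:, lidx].T @ z[:, uni_idx] / n1  # lnc x universe correlations
                upos = {g: k for k, g in enumerate(universe)}
                for i, lnc in enumerate(lnc_ok):
                    for gid in trans_targets[lnc.gene_id]:
                        r = rmat[i, upos[gid]]
                        if np.isfinite(r) and abs(r) > trans_r:
                            pairs.append(
                                CoexpressionPair(lnc.gene_id, gid, lab, "trans", float(r), None, n1)
                            )
    return pairs


def pairs_frame(pairs: list[CoexpressionPair]) -> pd.DataFrame:
    df = pd.DataFrame([p.__dict__ for p in pairs])
    if df.empty:
        df = pd.DataFrame(
            columns=["lncrna_id", "gene_id", "cluster", "mode", "pearson_r", "genomic_distance", "n_cells"]
        )
    return df


def summarize_pairs(
    pairs: list[CoexpressionPair] | pd.DataFrame,
    cluster_lineage_map: dict[str, str] | None = None,
    mode: str = "cis",
) -> dict:
    """Counts and half-up 1-decimal percentages per cluster (and lineage).

    Percentages are relative to the total number of ``mode`` pair records;
    an empty input produces a total of 0 and no percentages. The distinct
    (lncRNA, gene) pair count and member counts are reported alongside.
    """
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_frame(pairs)
    df = df[df["mode"] == mode] if "mode" in df.columns and len(df) else df
    total = int(len(df))
    out: dict = {
        "mode": mode,
        "total_pairs": total,
        "unique_pairs": int(df[["lncrna_id", "gene_id"]].drop_duplicates().shape[0]) if total else 0,
        "n_lncrnas": int(df["lncrna_id"].nunique()) if total else 0,
        "n_targets": int(df["gene_id"].nunique()) if total else 0,
        "per_cluster": {},
        "per_lineage": {},
    }
    if total == 0:
        return out
    counts = df.groupby("cluster").size().sort_index()
    out["per_cluster"] = {
        lab: {"count": int(c), "percent": round_half_up(100.0 * c / total, 1)}
        for lab, c in counts.items()
    }
    if cluster_lineage_map:
        lineage = df["cluster"].map(lambda c: cluster_lineage_map.get(c, "unassigned"))
        lcounts = df.groupby(lineage).size().sort_index()
        out["per_lineage"] = {
            lab: {"count": int(c), "percent": round_half_up(100.0 * c / total, 1)}
            for lab, c in lcounts.items()
        }
    return out
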