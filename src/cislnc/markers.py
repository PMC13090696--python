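"""Cluster marker detection and lncRNA/coding expression comparisons.

Markers are found one-vs-rest per cluster with a two-sided Wilcoxon rank-sum
test on log-normalized values (exact enumeration at small n, normal
approximation with tie and continuity correction otherwise), followed by
Benjamini-Hochberg adjustment within each cluster's transcript family; a
transcript is significant at adjusted p < 0.05. Biotype comparisons contrast
per-transcript summary distributions (median expression, percent of cells
expressing) between lncRNA and protein-coding transcripts with the
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from cislnc._stats import bh_adjust, rank_sum_test

ALPHA = 0.05
MIN_CLUSTER_CELLS = 3


@dataclass(frozen=True)
class MarkerResult:
    transcript_id: str
    cluster: str
    mean_in: float
    mean_out: float
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    pct_in: float
    pct_out: float

    @property
    def significant(self) -> bool:
        return self.adjusted_p < ALPHA


def _dense(norm: ad.AnnData) -> np.ndarray:
    x = norm.X
    return x.toarray() if sparse.issparse(x) else np.asarray(x, dtype=float)


def find_markers(norm: ad.AnnData, cluster_key: str = "cluster") -> list[MarkerResult]:
    """One-vs-rest Wilcoxon marker test for every (transcript, cluster).

    Clusters with fewer than 3 cells are skipped (recorded under
    ``norm.uns['skipped_clusters']``). BH adjustment is applied within each
    cluster across its transcript family.
    """
    clusters = norm.obs[cluster_key].astype(str)
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    x = _dense(norm)
    n_cells, n_tx = x.shape
    names = list(norm.var_names)

    usable = [lab for lab in labels if (clusters == lab).sum() >= MIN_CLUSTER_CELLS]
    skipped = [lab for lab in labels if lab not in usable]
    norm.uns["skipped_clusters"] = skipped

    results: list[MarkerResult] = []
    # global ranks per transcript serve every cluster's rank-sum statistic
    ranks = stats.rankdata(x, axis=0)
    rank_sums = {lab: ranks[(clusters == lab).to_numpy()].sum(axis=0) for lab in usable}
    # tie correction is shared across clusters for a given transcript
    tie_terms = np.empty(n_tx)
    for j in range(n_tx):
        _, counts = np.unique(x[:, j], return_counts=True)
        tie_terms[j] = (counts.astype(float) ** 3 - counts).sum()

    for lab in usable:
        mask = (clusters == lab).to_numpy()
        n1 = int(mask.sum())
        n2 = n_cells - n1
        mean_in = x[mask].mean(axis=0)
        mean_out = x[~mask].mean(axis=0)
        pct_in = (x[mask] > 0).mean(axis=0)
        pct_out = (x[~mask] > 0).mean(axis=0)
        expm_in = np.expm1(x[mask]).mean(axis=0)
        expm_out = np.expm1(x[~mask]).mean(axis=0)
        log2fc = np.log2((expm_in + 1.0) / (expm_out + 1.0))

        if max(n1, n2) <= 25:
            pvals = np.array([rank_sum_test(x[mask, j], x[~mask, j])[1] for j in range(n_tx)])
        else:
            w = rank_sums[lab]
            u = w - n1 * (n1 + 1) / 2.0
            mu = n1 * n2 / 2.0
            sigma2 = n1 * n2 / 12.0 * (n_cells + 1 - tie_terms / (n_cells * (n_cells - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (np.abs(u - mu) - 0.5) / np.sqrt(sigma2)
            z = np.where(sigma2 <= 0, 0.0, np.maximum(z, 0.0))
            pvals = np.where(sigma2 <= 0, 1.0, np.minimum(1.0, 2.0 * stats.norm.sf(z)))

        adj = bh_adjust(pvals)
        for j in range(n_tx):
            results.append(
                MarkerResult(
                    transcript_id=names[j],
                    cluster=lab,
                    mean_in=float(mean_in[j]),
                    mean_out=float(mean_out[j]),
                    log2_fold_change=float(log2fc[j]),
                    p_value=float(pvals[j]),
                    adjusted_p=float(adj[j]),
                    pct_in=float(pct_in[j]),
                    pct_out=float(pct_out[j]),
                )
            )
    return results


def markers_frame(results: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def top_transcripts(
    results: list[MarkerResult],
    n: int = 2000,
    mode: str = "marker_union",
    norm: ad.AnnData | None = None,
) -> list[str]:
    """The top-n transcript list.

    ``marker_union`` (default): de-duplicated significant cluster markers
    ordered by best adjusted p, then higher in-cluster mean, then id.
    ``expression``: all transcripts of ``norm`` ranked by overall mean
    normalized expression.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode == "expression":
        if norm is None:
            raise ValueError("expression mode needs the normalized matrix")
        means = _dense(norm).mean(axis=0)
        order = sorted(zip(norm.var_names, means), key=lambda t: (-t[1], t[0]))
        return [t for t, _ in order[:n]]
    if mode != "marker_union":
        raise ValueError(f"unknown mode {mode!r}")
    if not results:
        raise ValueError("no marker results supplied")
    best: dict[str, tuple[float, float]] = {}
    for r in results:
        if not r.significant:
            continue
        key = (r.adjusted_p, -r.mean_in)
        if r.transcript_id not in best or key < best[r.transcript_id]:
            best[r.transcript_id] = key
    ordered = sorted(best, key=lambda t: (best[t][0], best[t][1], t))
    return ordered[:n]


def biotype_comparison(norm: ad.AnnData, biotypes: dict[str, str] | None = None) -> dict:
    """Mann-Whitney comparison of lncRNA vs protein-coding transcript summaries.

    For every transcript, the median normalized expression over cells and the
    percent of cells expressing it (count > 0) are computed; each summary is
    compared between the two biotype groups with a two-sided Mann-Whitney U
    test.
    """
    if biotypes is None:
        biotypes = dict(zip(norm.var_names, norm.var["biotype"]))
    x = _dense(norm)
    med = np.median(x, axis=0)
    pct = (x > 0).mean(axis=0)
    groups = {"lncRNA": [], "protein_coding": []}
    for j, t in enumerate(norm.var_names):
        b = biotypes.get(t)
        if b in groups:
            groups[b].append(j)
    for b, idx in groups.items():
        if not idx:
            raise ValueError(f"biotype {b!r} not represented in the matrix")
    out = {"n_lncrna": len(groups["lncRNA"]), "n_coding": len(groups["protein_coding"])}
    for label, values in (("median_expression", med), ("pct_cells_expressing", pct)):
        a = values[groups["lncRNA"]]
        b = values[groups["protein_coding"]]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[label] = {
            "lncRNA_median": float(np.median(a)),
            "coding_median": float(np.median(b)),
            "U": float(res.statistic),
            "p_value": float(res.pvalue),
        }
    return out
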