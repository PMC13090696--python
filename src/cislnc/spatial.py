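"""Binarized spatial co-expression maps, domain summaries and stage trends.

Each transcript's per-bin counts are reduced to a boolean map — ``positive``
mode keeps bins with count > 0, ``quantile`` mode keeps bins above the q-th
quantile of that transcript's nonzero bin counts — and two maps merge into a
ternary-plus-one state per bin (both / only_a / only_b / neither). Domain
summaries report the fraction of each anatomical domain's bins in state
``both`` plus an enrichment ratio against the all-bin fraction. Stage trends
label a transcript increasing/decreasing only when its per-stage means are
strictly monotone. Cluster spatial correlation flags cluster-profile pairs
with Pearson r >= 0.7 at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

STATES = ("both", "only_a", "only_b", "neither")


def _column(bins: ad.AnnData, transcript: str) -> np.ndarray:
    if transcript not in bins.var_names:
        raise KeyError(f"transcript {transcript!r} not in matrix")
    j = bins.var_names.get_loc(transcript)
    col = bins.X[:, j]
    return np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()


def binarize(bins: ad.AnnData, transcript: str, mode: str = "positive", q: float = 0.75) -> np.ndarray:
    """Boolean per-bin expression call for one transcript.

    ``positive``: count > 0. ``quantile``: count > q-th quantile of the
    transcript's nonzero bin counts (all-false when the transcript is silent).
    """
    counts = _column(bins, transcript)
    if mode == "positive":
        return counts > 0
    if mode == "quantile":
        nz = counts[counts > 0]
        if len(nz) == 0:
            return np.zeros(len(counts), dtype=bool)
        return counts > np.quantile(nz, q)
    raise ValueError(f"unknown binarization mode {mode!r}")


@dataclass
class CoexpressionMap:
    """Per-bin co-expression state of a transcript pair."""

    a: str
    b: str
    states: pd.Series  # index = bin ids, values in STATES
    rule: str

    def state_counts(self) -> dict[str, int]:
        vc = self.states.value_counts()
        return {s: int(vc.get(s, 0)) for s in STATES}


def merge_pair(
    bins: ad.AnnData, a: str, b: str, mode: str = "positive", q: float = 0.75
) -> CoexpressionMap:
    """Merge two binarized maps into per-bin states both/only_a/only_b/neither."""
    ba = binarize(bins, a, mode, q)
    bb = binarize(bins, b, mode, q)
    state = np.where(ba & bb, "both", np.where(ba, "only_a", np.where(bb, "only_b", "neither")))
    return CoexpressionMap(
        a=a, b=b, states=pd.Series(state, index=bins.obs_names), rule=f"{mode}(q={q})"
    )


def domain_summary(cmap: CoexpressionMap, bins: ad.AnnData, domain_key: str = "domain") -> dict:
    """Fraction of bins in state ``both`` per domain plus enrichment ratios.

    The ratio divides a domain's both-fraction by the all-bin both-fraction;
    an empty domain reports ``None`` rather than 0. The weighted average of
    domain fractions recomposes the global fraction exactly.
    """
    domains = bins.obs[domain_key].astype(str)
    both = (cmap.states == "both").to_numpy()
    global_frac = float(both.mean()) if len(both) else float("nan")
    out = {"global_both_fraction": global_frac, "domains": {}}
    for d in sorted(domains.unique()):
        mask = (domains == d).to_numpy()
        n = int(mask.sum())
        if n == 0:
            out["domains"][d] = {"n_bins": 0, "both_fraction": None, "enrichment": None}
            continue
        frac = float(both[mask].mean())
        enrich = frac / global_frac if global_frac > 0 else None
        out["domains"][d] = {"n_bins": n, "both_fraction": frac, "enrichment": enrich}
    return out


@dataclass(frozen=True)
class StageTrend:
    transcript_id: str
    stage_means: dict[str, float]
    direction: str  # increasing | decreasing | non-monotone


def stage_trend(
    norm: ad.AnnData, transcript: str, stage_key: str = "stage", stage_order: list[str] | None = None
) -> StageTrend:
    """Mean expression per stage in stage order; strict monotonicity labels the direction."""
    values = _column(norm, transcript)
    stages = norm.obs[stage_key].astype(str)
    present = list(dict.fromkeys(stage_order)) if stage_order else sorted(stages.unique())
    present = [s for s in present if (stages == s).any()]
    if len(present) < 2:
        raise ValueError("stage trend needs at least 2 populated stages")
    means = {s: float(values[(stages == s).to_numpy()].mean()) for s in present}
    seq = [means[s] for s in present]
    if all(b > a for a, b in zip(seq, seq[1:])):
        direction = "increasing"
    elif all(b < a for a, b in zip(seq, seq[1:])):
        direction = "decreasing"
    else:
        direction = "non-monotone"
    return StageTrend(transcript, means, direction)


def cluster_spatial_correlation(
    cluster_profiles: pd.DataFrame, threshold_r: float = 0.7, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Pearson correlations between cluster mean-expression profiles.

    Returns a frame (cluster_a, cluster_b, r, p_value, flagged) for every
    unordered pair; a pair is flagged when r >= threshold_r and p < alpha.
    Zero-variance profiles are omitted with reason rows (r and p NaN).
    """
    labels = list(cluster_profiles.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 cluster profiles")
    x = cluster_profiles.to_numpy(dtype=float)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = x[i], x[j]
            if a.std() == 0 or b.std() == 0:
                rows.append((labels[i], labels[j], np.nan, np.nan, False, "zero variance"))
                continue
            r, p = stats.pearsonr(a, b)
            rows.append((labels[i], labels[j], float(r), float(p), bool(r >= threshold_r and p < alpha), ""))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "r", "p_value", "flagged", "note"])


def cluster_profiles(norm: ad.AnnData, cluster_key: str = "cluster") -> pd.DataFrame:
    """Cluster x transcript mean normalized expression matrix."""
    x = norm.X.toarray() if sparse.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    clusters = norm.obs[cluster_key].astype(str).to_numpy()
    labels = sorted(set(clusters))
    rows = [x[clusters == lab].mean(axis=0) for lab in labels]
    return pd.DataFrame(rows, index=labels, columns=norm.var_names)
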