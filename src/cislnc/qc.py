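"""Cell-level QC filters, log-normalization and cell-cycle module scoring.

The QC gates keep cells with total UMIs strictly below ``max_umi``,
mitochondrial fraction strictly below ``max_mito`` and a detected-gene count
inside ``[min_genes, max_genes]`` (detected = raw count > 0). Normalization is
the global-scaling log transform ``log(1 + scale_factor * count / total)``
(natural log). Cell-cycle phases are scored as module scores — mean normalized
expression of a phase gene set minus that of an expression-matched control set
drawn from average-expression bins — and cells whose highest phase score falls
below a cutoff (default 0.3) are called non-cycling.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

DEFAULT_SCALE_FACTOR = 10_000.0
DEFAULT_CYCLE_CUTOFF = 0.3
MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QcThresholds:
    """Cell filters: keep UMI < max_umi, mito < max_mito, min_genes <= detected <= max_genes."""

    max_umi: int = 8000
    max_mito: float = 0.10
    min_genes: int = 500
    max_genes: int = 4000

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in [0, 1]")


def _counts_matrix(adata: ad.AnnData) -> sparse.csr_matrix:
    x = adata.X
    return x.tocsr() if sparse.issparse(x) else sparse.csr_matrix(x)


def mito_fraction(adata: ad.AnnData, prefix: str = MITO_PREFIX) -> np.ndarray:
    """Per-cell mitochondrial fraction: metadata column if present, else
    computed from transcript ids starting with ``prefix``."""
    if "mito_frac" in adata.obs:
        return adata.obs["mito_frac"].to_numpy(dtype=float)
    x = _counts_matrix(adata)
    total = np.asarray(x.sum(axis=1)).ravel()
    is_mito = adata.var_names.str.startswith(prefix)
    mito = np.asarray(x[:, np.flatnonzero(is_mito)].sum(axis=1)).ravel() if is_mito.any() else np.zeros(len(total))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_cells(
    raw: ad.AnnData, thr: QcThresholds = QcThresholds()
) -> tuple[ad.AnnData, dict[str, int]]:
    """Apply the three QC gates; returns the filtered AnnData and a per-gate report.

    Cell order and the transcript set are preserved. An empty result is legal
    (reported, not raised).
    """
    x = _counts_matrix(raw)
    umi = np.asarray(x.sum(axis=1)).ravel()
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    mito = mito_fraction(raw)

    pass_umi = umi < thr.max_umi
    pass_mito = mito < thr.max_mito
    pass_genes = (detected >= thr.min_genes) & (detected <= thr.max_genes)
    keep = pass_umi & pass_mito & pass_genes

    report = {
        "cells_in": int(raw.n_obs),
        "cells_out": int(keep.sum()),
        "failed_umi": int((~pass_umi).sum()),
        "failed_mito": int((~pass_mito).sum()),
        "failed_genes": int((~pass_genes).sum()),
    }
    return raw[keep].copy(), report


def lognormalize(filtered: ad.AnnData, scale_factor: float = DEFAULT_SCALE_FACTOR) -> ad.AnnData:
    """log(1 + scale_factor * count / total) per cell; totals must be positive."""
    x = _counts_matrix(filtered).astype(float)
    total = np.asarray(x.sum(axis=1)).ravel()
    if (total <= 0).any():
        bad = filtered.obs_names[int(np.flatnonzero(total <= 0)[0])]
        raise ValueError(f"cell {bad!r} has zero total counts and cannot be normalized")
    scaled = x.multiply(scale_factor / total[:, None]).tocsr()
    scaled.data = np.log1p(scaled.data)
    out = filtered.copy()
    out.X = scaled
    out.uns["scale_factor"] = float(scale_factor)
    return out


def _dense(norm: ad.AnnData) -> np.ndarray:
    x = norm.X
    return x.toarray() if sparse.issparse(x) else np.asarray(x, dtype=float)


def score_cell_cycle(
    norm: ad.AnnData,
    phase_sets: dict[str, list[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    cutoff: float = DEFAULT_CYCLE_CUTOFF,
) -> pd.DataFrame:
    """Module score per phase and cell, plus max_score / non_cycling columns.

    For each phase, every transcript is assigned to one of ``n_bins`` bins of
    average normalized expression; ``n_ctrl`` control transcripts are sampled
    (seeded, with replacement) from the bin of each phase gene, and the score
    is mean(phase genes) - mean(controls). Phase genes missing from the matrix
    are dropped with a warning entry; a phase set that empties out raises.
    """
    x = _dense(norm)
    names = list(norm.var_names)
    name_pos = {n: i for i, n in enumerate(names)}
    avg = x.mean(axis=0)

    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(names), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in range(n_bins)
    }

    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(index=norm.obs_names)
    dropped: list[str] = []
    for phase in sorted(phase_sets):
        idx = []
        for t in phase_sets[phase]:
            if t in name_pos:
                idx.append(name_pos[t])
            else:
                dropped.append(f"{phase}:{t}")
        if not idx:
            raise ValueError(f"phase set {phase!r} has no transcripts present in the matrix")
        ctrl: set[int] = set()
        for i in idx:
            bin_members = members[bin_of[i]]
            if len(bin_members) <= n_ctrl:
                ctrl.update(int(j) for j in bin_members)
            else:
                ctrl.update(int(j) for j in rng.choice(bin_members, size=n_ctrl, replace=False))
        ctrl_idx = sorted(ctrl)
        scores[phase] = x[:, idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)

    scores["max_score"] = scores.max(axis=1)
    scores["non_cycling"] = scores["max_score"] < cutoff
    scores.attrs["dropped"] = dropped
    return scores


def drop_cycling(
    scores: pd.DataFrame, expr: ad.AnnData, cutoff: float = DEFAULT_CYCLE_CUTOFF
) -> ad.AnnData:
    """Keep exactly the cells whose highest phase score is below ``cutoff``."""
    missing = expr.obs_names.difference(scores.index)
    if len(missing):
        raise ValueError(f"scores missing for {len(missing)} cells, e.g. {missing[0]!r}")
    phase_cols = [c for c in scores.columns if c not in ("max_score", "non_cycling")]
    max_score = scores.loc[expr.obs_names, phase_cols].max(axis=1)
    keep = (max_score < cutoff).to_numpy()
    return expr[keep].copy()
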