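"""Reading and writing the on-disk exchange formats.

Expression matrices travel as 10x-style MatrixMarket bundles — ``matrix.mtx``
(features x cells), ``features.tsv`` (id, name, biotype), ``barcodes.tsv`` —
plus a ``cell_metadata.tsv`` sidecar (cell_id, cluster, stage, mito_frac).
Spatial data use the same bundle with a ``spatial_bins.tsv`` sidecar
(bin_id, x, y, domain, stage). In memory everything is an
:class:`anndata.AnnData` (cells/bins in ``obs``, transcripts in ``var``).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

CELL_META_COLUMNS = ["cell_id", "cluster", "stage", "mito_frac"]
BIN_META_COLUMNS = ["bin_id", "x", "y", "domain", "stage"]


def write_mtx_bundle(adata: ad.AnnData, outdir, meta_name: str = "cell_metadata.tsv") -> None:
    """Write an AnnData as a features-x-cells MatrixMarket bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = sparse.csc_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", x.T.astype(np.int64) if np.issubdtype(x.dtype, np.integer) else x.T)
    feat = pd.DataFrame(
        {
            "id": adata.var_names,
            "name": adata.var_names,
            "biotype": adata.var.get("biotype", pd.Series("", index=adata.var_names)),
        }
    )
    feat.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if meta_name == "cell_metadata.tsv":
        meta = pd.DataFrame(
            {
                "cell_id": adata.obs_names,
                "cluster": adata.obs.get("cluster", ""),
                "stage": adata.obs.get("stage", ""),
                "mito_frac": adata.obs.get("mito_frac", np.nan),
            }
        )
    else:
        meta = pd.DataFrame(
            {
                "bin_id": adata.obs_names,
                "x": adata.obs["x"],
                "y": adata.obs["y"],
                "domain": adata.obs["domain"],
                "stage": adata.obs["stage"],
            }
        )
    meta.to_csv(outdir / meta_name, sep="\t", index=False)


def read_mtx_bundle(indir, meta_name: str = "cell_metadata.tsv") -> ad.AnnData:
    """Read a features-x-cells MatrixMarket bundle back into an AnnData."""
    indir = Path(indir)
    x = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    feat = pd.read_csv(indir / "features.tsv", sep="\t", header=None, names=["id", "name", "biotype"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    meta = pd.read_csv(indir / meta_name, sep="\t")
    id_col = meta.columns[0]
    meta = meta.set_index(id_col, drop=False)
    meta.index = meta.index.astype(str)
    meta = meta.loc[barcodes]
    var = pd.DataFrame({"biotype": feat["biotype"].values}, index=feat["id"].astype(str))
    obs = meta.drop(columns=[id_col])
    obs.index.name = None
    adata = ad.AnnData(X=x, obs=obs, var=var)
    adata.obs_names = barcodes.values
    return adata


def write_phase_sets(phase_sets: dict[str, list[str]], path) -> None:
    """Two-column TSV (phase, transcript_id), one row per phase gene."""
    rows = [(phase, t) for phase in sorted(phase_sets) for t in phase_sets[phase]]
    pd.DataFrame(rows, columns=["phase", "transcript_id"]).to_csv(path, sep="\t", index=False)


def read_phase_sets(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {phase: grp["transcript_id"].tolist() for phase, grp in df.groupby("phase", sort=True)}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
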