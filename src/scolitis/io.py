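"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices travel as Matrix-Market triplets with ``features.tsv`` /
``barcodes.tsv`` sidecars (CellRanger-style, genes as rows) plus a
``cells.csv`` metadata table.  TCR input is the 10X "filtered contig
annotations" CSV dialect; histology input is a tidy per-image count CSV.
"""

from __future__ import annotations

import json
import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONTIG_COLUMNS = [
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "raw_clonotype_id",
]

HISTOLOGY_COLUMNS = [
    "image_id",
    "patient",
    "cohort",
    "probe",
    "compartment",
    "count",
    "dapi_total",
]


def write_mtx_dir(adata: ad.AnnData, outdir: str) -> None:
    """Write counts as matrix.mtx (genes x cells) + features.tsv + barcodes.tsv + cells.csv."""
    os.makedirs(outdir, exist_ok=True)
    mat = sp.csc_matrix(adata.X.T)  # genes x cells, column-major like CellRanger
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    adata.obs.to_csv(os.path.join(outdir, "cells.csv"), index_label="barcode")


def read_mtx_dir(indir: str) -> ad.AnnData:
    """Read a directory written by :func:`write_mtx_dir` back into AnnData."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    x = sp.csr_matrix(mat.T)
    adata = ad.AnnData(X=x)
    adata.var_names = genes.astype(str).to_list()
    adata.obs_names = barcodes.astype(str).to_list()
    cells_path = os.path.join(indir, "cells.csv")
    if os.path.exists(cells_path):
        obs = pd.read_csv(cells_path, index_col="barcode")
        adata.obs = obs.loc[adata.obs_names]
    return adata


def write_contigs(tables: dict[str, pd.DataFrame], outdir: str) -> None:
    """Write one filtered_contig_annotations.csv per patient under outdir/<patient>/."""
    for patient, table in tables.items():
        pdir = os.path.join(outdir, patient)
        os.makedirs(pdir, exist_ok=True)
        table[CONTIG_COLUMNS].to_csv(
            os.path.join(pdir, "filtered_contig_annotations.csv"), index=False
        )


def read_contigs(path: str) -> pd.DataFrame:
    """Read a filtered-contig CSV; boolean-ish columns are kept as strings ("true"/"false")."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig table {path} lacks required columns: {missing}")
    return df


def write_histology(counts: pd.DataFrame, path: str) -> None:
    counts[HISTOLOGY_COLUMNS].to_csv(path, index=False)


def read_histology(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in HISTOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"histology table {path} lacks required columns: {missing}")
    return df


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.reset_index().to_dict(orient="list")}
    if isinstance(obj, pd.Series):
        return {"__series__": {"index": list(obj.index.astype(str)), "values": obj.to_list()}}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth(truth, path: str) -> None:
    """Serialize a SyntheticTruth bundle to JSON (tables as column lists)."""
    payload = {}
    for name in ("cells", "clonotypes", "cell_clusters", "histology_log_rr"):
        value = getattr(truth, name, None)
        if value is not None:
            payload[name] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_jsonable)
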