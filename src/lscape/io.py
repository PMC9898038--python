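"""Standard-format IO: MTX count trios, gene sets, pair lists, tables, config.

Single-cell counts travel as a 10x-style trio — ``matrix.mtx`` (genes x cells,
1-based MatrixMarket), ``features.tsv`` (gene ids) and ``metadata.tsv`` (cell
ids plus per-cell metadata).  Identifiers are plain strings matched exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse


class IOError_(ValueError):
    pass


def write_cellmatrix(adata: ad.AnnData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    if adata.uns:
        serializable = {k: v for k, v in adata.uns.items()
                        if isinstance(v, (dict, list, str, int, float))}
        (outdir / "annotations.json").write_text(json.dumps(serializable, indent=1))


def read_cellmatrix(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    try:
        mat = scio.mmread(indir / "matrix.mtx")
    except Exception as exc:
        raise IOError_(f"cannot parse {indir / 'matrix.mtx'}: {exc}") from exc
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t",
                       dtype={"cell_id": str}).set_index("cell_id")
    if mat.shape[0] != len(genes):
        raise IOError_(f"matrix has {mat.shape[0]} genes but features.tsv lists {len(genes)}")
    if mat.shape[1] != len(meta):
        raise IOError_(f"matrix has {mat.shape[1]} cells but metadata.tsv lists {len(meta)}")
    X = sparse.csr_matrix(mat.T)
    adata = ad.AnnData(X=X, obs=meta, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    ann = indir / "annotations.json"
    if ann.exists():
        adata.uns.update(json.loads(ann.read_text()))
    return adata


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in genes]
    pd.DataFrame(rows, columns=["set", "gene"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {name: sub["gene"].astype(str).tolist() for name, sub in df.groupby("set", sort=False)}


def write_lr_pairs(pairs: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


def read_lr_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(df[["ligand", "receptor"]].itertuples(index=False, name=None))


def read_bulk(path: str | Path) -> pd.DataFrame:
    """Bulk expression, samples x genes, first column = sample id."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise IOError_(f"survival table missing columns {sorted(missing)}")
    return df.set_index("sample")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise IOError_("config must be a mapping")
    return cfg
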