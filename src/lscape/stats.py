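"""Shared differential-expression statistics.

One place for the Wilcoxon rank-sum (Mann-Whitney, asymptotic with continuity
and tie correction) gene tables used by surface-marker discovery, signature
building and longitudinal differential expression, with Benjamini-Hochberg
correction across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

_CHUNK = 512


def _dense(block) -> np.ndarray:
    return block.toarray() if sparse.issparse(block) else np.asarray(block)


def rank_sum_table(normalized, mask_a: np.ndarray, mask_b: np.ndarray,
                   gene_names) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of group A vs group B.

    ``normalized`` is cells x genes log-normalized expression; log fold change
    is the difference of group means on that log scale.  Returns a DataFrame
    indexed by gene with ``logfc``, ``p`` and BH-``fdr`` columns (gene order
    preserved; results do not depend on cell order).
    """
    gene_names = np.asarray(gene_names)
    n_genes = normalized.shape[1]
    logfc = np.empty(n_genes)
    pvals = np.empty(n_genes)
    for lo in range(0, n_genes, _CHUNK):
        hi = min(lo + _CHUNK, n_genes)
        a = _dense(normalized[mask_a, lo:hi])
        b = _dense(normalized[mask_b, lo:hi])
        logfc[lo:hi] = a.mean(axis=0) - b.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                method="asymptotic")
        pvals[lo:hi] = p
    pvals = np.nan_to_num(pvals, nan=1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"logfc": logfc, "p": pvals, "fdr": fdr},
                        index=pd.Index(gene_names, name="gene"))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
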