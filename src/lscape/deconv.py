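"""Signature-matrix construction and bulk deconvolution by non-negative least squares.

A genes x states signature of linear-scale mean expression is built from
labeled single cells (one-vs-rest rank-sum marker selection per state); each
bulk profile is then decomposed over the signature columns with NNLS and the
coefficients renormalized to proportions.  The solver is deterministic and its
accuracy is validated against mixtures of known composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import nnls
from scipy.stats import wilcoxon

from .stats import rank_sum_table

log = logging.getLogger("lscape")


class DeconvolutionError(ValueError):
    pass


@dataclass
class SignatureMatrix:
    matrix: pd.DataFrame       # genes x states, linear-scale means
    marker_table: pd.DataFrame  # gene, state, logfc, fdr for selected markers


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # samples x states, rows sum to 1
    residuals: pd.Series


def build_signature(normalized, gene_names, states: pd.Series,
                    top_m: int = 50, max_fdr: float = 0.05,
                    min_cells: int = 3) -> SignatureMatrix:
    """Select per-state markers and average their linear-scale expression.

    Per state, genes passing one-vs-rest rank-sum BH-FDR <= ``max_fdr`` with
    positive logFC are ranked by logFC and the ``top_m`` kept; signature
    entries are per-state means of expm1(log-normalized) expression over the
    union of all selected genes.
    """
    states = states.astype(str)
    usable = [st for st in sorted(states.unique())
              if (states == st).sum() >= min_cells]
    if len(usable) < 2:
        raise DeconvolutionError("need >= 2 states with enough cells")
    gene_names = np.asarray(gene_names)
    selected: dict[str, pd.DataFrame] = {}
    for st in usable:
        mask_a = (states == st).to_numpy()
        tab = rank_sum_table(normalized, mask_a, ~mask_a, gene_names)
        cand = tab[(tab["fdr"] <= max_fdr) & (tab["logfc"] > 0)]
        if cand.empty:
            raise DeconvolutionError(
                f"state {st!r} yields no significant marker; lower stringency")
        selected[st] = cand.sort_values("logfc", ascending=False).head(top_m)
    union = sorted(set().union(*[set(v.index) for v in selected.values()]))
    col_of = {g: i for i, g in enumerate(gene_names)}
    cols = [col_of[g] for g in union]
    lin = normalized[:, cols]
    lin = lin.toarray() if sparse.issparse(lin) else np.asarray(lin)
    lin = np.expm1(lin)
    sig = {}
    for st in usable:
        sig[st] = lin[(states == st).to_numpy()].mean(axis=0)
    matrix = pd.DataFrame(sig, index=pd.Index(union, name="gene"))
    marker_rows = []
    for st, tab in selected.items():
        for gene, r in tab.iterrows():
            marker_rows.append((gene, st, r["logfc"], r["fdr"]))
    return SignatureMatrix(
        matrix=matrix,
        marker_table=pd.DataFrame(marker_rows, columns=["gene", "state", "logfc", "fdr"]),
    )


def deconvolve(bulk: pd.DataFrame, sig: SignatureMatrix) -> DeconvolutionResult:
    """Estimate state proportions for each bulk sample (samples x genes).

    Bulk and signature are restricted to shared genes and brought to a common
    total-expression level before NNLS (the bulk vector is rescaled onto the
    signature's mean column total, which preserves mixture linearity);
    coefficients are renormalized to sum to 1.  Proportions are invariant to
    positive rescaling of a bulk sample.
    """
    shared = [g for g in sig.matrix.index if g in bulk.columns]
    if len(shared) == 0:
        raise DeconvolutionError("bulk shares no genes with the signature")
    if len(shared) < 0.5 * len(sig.matrix.index):
        log.warning("deconvolve: only %d/%d signature genes present in bulk",
                    len(shared), len(sig.matrix.index))
    S = sig.matrix.loc[shared].to_numpy(dtype=float)
    level = S.sum(axis=0).mean()
    props, resid = {}, {}
    for sample, row in bulk[shared].iterrows():
        b = row.to_numpy(dtype=float)
        if b.sum() <= 0:
            raise DeconvolutionError(f"bulk sample {sample!r} is all zero over shared genes")
        b_scaled = b * (level / b.sum())
        coef, rnorm = nnls(S, b_scaled)
        total = coef.sum()
        if total == 0:
            raise DeconvolutionError(f"NNLS returned all-zero coefficients for {sample!r}")
        props[sample] = coef / total
        resid[sample] = rnorm
    prop_df = pd.DataFrame(props, index=sig.matrix.columns).T
    return DeconvolutionResult(proportions=prop_df,
                               residuals=pd.Series(resid, name="residual"))


def paired_shift_test(pre: pd.DataFrame, post: pd.DataFrame,
                      state: str) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired pre/post proportions of one state.

    Exact distribution for n <= 25 pairs, normal approximation above.  When
    every paired difference is zero the comparison carries no information and
    (nan, 1.0) is returned with a warning.
    """
    common = pre.index.intersection(post.index)
    if len(common) == 0:
        raise DeconvolutionError("no matched sample pairs")
    if len(common) < 5:
        log.warning("paired_shift_test: only %d pairs; power is low", len(common))
    d = (post.loc[common, state] - pre.loc[common, state]).to_numpy(dtype=float)
    if np.all(d == 0):
        log.warning("paired_shift_test: all paired differences are zero (no information)")
        return float("nan"), 1.0
    method = "exact" if len(d) <= 25 else "approx"
    stat, p = wilcoxon(d, zero_method="wilcox", method=method)
    return float(stat), float(p)
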