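"""Label transfer to longitudinal samples and the PSP->QSC reprogramming index.

Post-treatment cells are mapped into the reference PC space (using the stored
HVG set, per-gene scaling and loadings) and labeled by k-nearest-neighbor
majority vote.  Composition shifts and per-state differential expression
quantify the treatment response, and a ratio-of-distances reprogramming index
R measures how far the post-treatment PSP centroid has moved from the
pre-treatment PSP centroid toward the pre-treatment QSC centroid in
differential-gene z-space: R = 0 (unchanged PSP) .. 1 (fully QSC-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .preprocess import EmbeddingResult, normalize_log
from .stats import rank_sum_table
from .synthetic import STATE_ORDER

log = logging.getLogger("lscape")

MIN_SHARED_GENES = 200


class LongitudinalError(ValueError):
    pass


@dataclass
class TransferResult:
    labels: pd.Series        # per query cell
    confidence: pd.Series    # winning vote fraction, in (0, 1]


@dataclass
class ShiftTable:
    proportions: pd.DataFrame   # states x {pre, post, delta}
    flow: pd.DataFrame          # state_pre x state_post transition counts


@dataclass
class ReprogrammingIndex:
    r: float
    centroids: pd.DataFrame     # rows pre_QSC / pre_PSP / post_PSP in DE z-space
    de_genes: list[str]


def transfer_labels(reference_labels: pd.Series, ref_obs_names,
                    emb: EmbeddingResult, query: ad.AnnData,
                    k: int = 15) -> TransferResult:
    """Project query cells onto the reference PCs and vote among k nearest
    labeled reference cells.

    ``reference_labels`` is indexed by reference cell ids (a subset of
    ``ref_obs_names``, the cell order underlying ``emb``).  Ties break by
    smaller mean neighbor distance, then by the fixed state order.
    """
    if len(reference_labels) < k:
        raise LongitudinalError(f"need at least k={k} labeled reference cells")
    shared = sum(g in set(emb.gene_names) for g in query.var_names)
    if shared < MIN_SHARED_GENES:
        raise LongitudinalError(
            f"query shares only {shared} genes with the reference (< {MIN_SHARED_GENES})")
    qn = normalize_log(query)
    q_pcs = emb.project(qn, query.var_names.to_numpy())
    pos_of = {c: i for i, c in enumerate(ref_obs_names)}
    try:
        ref_pos = np.asarray([pos_of[c] for c in reference_labels.index])
    except KeyError as exc:
        raise LongitudinalError(f"labeled cell {exc} not in the reference") from exc
    ref_pcs = emb.pcs[ref_pos]
    labels_arr = reference_labels.to_numpy()
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    dist, idx = nn.kneighbors(q_pcs)
    state_rank = {s: i for i, s in enumerate(STATE_ORDER)}
    out_labels, out_conf = [], []
    for row_idx, row_dist in zip(idx, dist):
        votes: dict[str, int] = {}
        dsum: dict[str, float] = {}
        for j, dj in zip(row_idx, row_dist):
            lab = labels_arr[j]
            votes[lab] = votes.get(lab, 0) + 1
            dsum[lab] = dsum.get(lab, 0.0) + dj
        best = sorted(votes,
                      key=lambda s: (-votes[s], dsum[s] / votes[s],
                                     state_rank.get(s, len(state_rank))))[0]
        out_labels.append(best)
        out_conf.append(votes[best] / k)
    return TransferResult(
        labels=pd.Series(out_labels, index=query.obs_names, name="state"),
        confidence=pd.Series(out_conf, index=query.obs_names, name="confidence"),
    )


def composition_shift(states_pre: pd.Series, states_post: pd.Series,
                      state_order: list[str] | None = None,
                      flow_pairs: pd.DataFrame | None = None) -> ShiftTable:
    """Pre/post proportion vectors, deltas and (optionally) a flow table.

    ``flow_pairs`` may give per-cell matched (state_pre, state_post) labels —
    e.g. transfer labels of the same residual cells — to fill the Sankey-style
    transition counts; otherwise the flow is the outer product expectation.
    """
    if len(states_pre) == 0 or len(states_post) == 0:
        raise LongitudinalError("both timepoints must be nonempty")
    order = list(state_order or STATE_ORDER)
    p_pre = states_pre.value_counts(normalize=True).reindex(order).fillna(0.0)
    p_post = states_post.value_counts(normalize=True).reindex(order).fillna(0.0)
    props = pd.DataFrame({"pre": p_pre, "post": p_post})
    props["delta"] = props["post"] - props["pre"]
    if flow_pairs is not None:
        flow = pd.crosstab(flow_pairs["state_pre"], flow_pairs["state_post"]
                           ).reindex(index=order, columns=order).fillna(0).astype(int)
    else:
        n_post = len(states_post)
        flow = pd.DataFrame(np.outer(p_pre.to_numpy(), p_post.to_numpy()) * n_post,
                            index=order, columns=order).round().astype(int)
    return ShiftTable(proportions=props, flow=flow)


def state_de(normalized_pre, normalized_post, gene_names,
             min_logfc: float = 0.25, max_fdr: float = 0.05,
             min_cells: int = 3, state: str = "") -> pd.DataFrame:
    """Post-vs-pre differential expression within one cellular state.

    Inputs are the log-normalized expression of that state's cells at each
    timepoint.  Returns genes passing |logFC| >= ``min_logfc`` and BH-FDR <=
    ``max_fdr``, logFC signed post minus pre.
    """
    if normalized_pre.shape[0] < min_cells or normalized_post.shape[0] < min_cells:
        raise LongitudinalError(
            f"state {state or '?'}: need >= {min_cells} cells at each timepoint")
    both = sparse.vstack([sparse.csr_matrix(normalized_post),
                          sparse.csr_matrix(normalized_pre)])
    mask_post = np.zeros(both.shape[0], dtype=bool)
    mask_post[: normalized_post.shape[0]] = True
    tab = rank_sum_table(both, mask_post, ~mask_post, gene_names)
    keep = tab[(tab["logfc"].abs() >= min_logfc) & (tab["fdr"] <= max_fdr)]
    return keep.sort_values("logfc", ascending=False)


def reprogramming_index(norm_pre_qsc, norm_pre_psp, norm_post_psp,
                        gene_names, de_genes) -> ReprogrammingIndex:
    """Ratio-of-distances index R = d(X,P) / (d(X,P) + d(X,Q)).

    Q, P, X are the pre-QSC, pre-PSP and post-PSP centroids in the space of
    ``de_genes``, z-scaled with pooled pre-treatment statistics so a global
    post-treatment shift cannot drive the index.
    """
    de_genes = [g for g in de_genes if g in set(np.asarray(gene_names))]
    if not de_genes:
        raise LongitudinalError("de_genes is empty (or none present in the matrix)")
    for m, nm in ((norm_pre_qsc, "pre-QSC"), (norm_pre_psp, "pre-PSP"),
                  (norm_post_psp, "post-PSP")):
        if m.shape[0] < 3:
            raise LongitudinalError(f"need >= 3 {nm} cells")
    gene_names = np.asarray(gene_names)
    col_of = {g: i for i, g in enumerate(gene_names)}
    cols = [col_of[g] for g in de_genes]

    def dense(m):
        sub = m[:, cols]
        return sub.toarray() if sparse.issparse(sub) else np.asarray(sub)

    q, p, x = dense(norm_pre_qsc), dense(norm_pre_psp), dense(norm_post_psp)
    pooled = np.vstack([q, p])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    cq = (q.mean(axis=0) - mu) / sd
    cp = (p.mean(axis=0) - mu) / sd
    cx = (x.mean(axis=0) - mu) / sd
    if np.allclose(cq, cp):
        raise LongitudinalError("pre-QSC and pre-PSP centroids coincide; axis undefined")
    d_xp = float(np.linalg.norm(cx - cp))
    d_xq = float(np.linalg.norm(cx - cq))
    r = d_xp / (d_xp + d_xq)
    centroids = pd.DataFrame([cq, cp, cx], index=["pre_QSC", "pre_PSP", "post_PSP"],
                             columns=de_genes)
    return ReprogrammingIndex(r=r, centroids=centroids, de_genes=list(de_genes))
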