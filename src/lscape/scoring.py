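"""Per-cell scores and assignment of leukemia-like cells to six cellular states.

Scores follow the standard single-cell constructions: binned-control module
scores for proliferation and cell-cycle programs; a transcriptional-diversity
stemness score (expressed-gene richness correlated genes, kNN-smoothed,
rank-scaled to [0, 1]); single-sample gene-set enrichment for named
signatures.  Leukemia-like cells are then assigned to QSC, PSP, GMP, PG,
promono or mono by a deterministic rule: argmax lineage program, a
proliferation threshold separating quiescent (QSC) from proliferating (PSP)
stem cells, and cell-cycle phase separating proliferating granulocytes (PG)
from GMP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .stats import rank_sum_table

log = logging.getLogger("lscape")

LINEAGE_PRIORITY = ["stem", "GMP", "granulocyte", "promono", "mono"]


class ScoringError(ValueError):
    pass


def _dense_cols(normalized, cols) -> np.ndarray:
    sub = normalized[:, cols]
    return sub.toarray() if sparse.issparse(sub) else np.asarray(sub)


def module_score(normalized, gene_names, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Mean set expression minus matched-bin control expression, per cell.

    Genes are binned into ``n_bins`` expression-matched bins by their average
    expression; for every set gene, ``n_ctrl`` control genes are sampled (with
    replacement) from its bin.  Deterministic for a fixed seed.
    """
    gene_names = np.asarray(gene_names)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    idx = [name_to_idx[g] for g in gene_set if g in name_to_idx]
    missing = [g for g in gene_set if g not in name_to_idx]
    if not idx:
        raise ScoringError(f"no gene of the set is present (missing e.g. {missing[:5]})")
    mean_expr = np.asarray(normalized.mean(axis=0)).ravel()
    order = rankdata(mean_expr, method="ordinal") - 1
    bin_of = (order * n_bins // len(gene_names)).astype(int)
    rng = np.random.default_rng(seed)
    w = np.zeros(len(gene_names))
    for gi in idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        draw = rng.choice(pool, size=n_ctrl, replace=True)
        np.add.at(w, draw, 1.0)
    set_mean = _dense_cols(normalized, idx).mean(axis=1)
    # control mean as a weighted matvec (columns enter with their multiplicity)
    ctrl_mean = np.asarray(normalized @ (w / w.sum())).ravel()
    return set_mean - ctrl_mean


def cycle_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """G1 if both scores <= 0, otherwise the larger of S / G2M."""
    s = np.asarray(s_score)
    g = np.asarray(g2m_score)
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    return phase.astype(object)


def _diffuse(s: np.ndarray, knn_graph: sparse.spmatrix, alpha: float,
             steps: int) -> np.ndarray:
    """Graph diffusion s <- (1-alpha) s + alpha A_hat s (row-normalized A)."""
    if alpha <= 0 or steps <= 0:
        return s
    adj = sparse.csr_matrix(knn_graph, dtype=float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    a_hat = sparse.diags(1.0 / deg) @ adj
    for _ in range(steps):
        s = (1.0 - alpha) * s + alpha * (a_hat @ s)
    return s


def _rank_scale(x: np.ndarray) -> np.ndarray:
    n = len(x)
    if n == 1:
        return np.array([0.5])
    r = rankdata(x, method="average")
    return (r - 1.0) / (n - 1.0)


def stemness_score(normalized, knn_graph: sparse.spmatrix, top_k: int = 200,
                   smooth_alpha: float = 0.5, smooth_steps: int = 3) -> np.ndarray:
    """Transcriptional-diversity stemness score in [0, 1].

    (i) per-cell expressed-gene richness; (ii) Pearson correlation of every
    gene with richness; (iii) mean expression of the ``top_k`` most correlated
    genes; (iv) diffusion smoothing over the kNN graph,
    ``s <- (1-alpha) s + alpha A_hat s``; (v) rank-scaling to [0, 1].
    """
    X = sparse.csr_matrix(normalized)
    n_cells, n_genes = X.shape
    gc = X.getnnz(axis=1).astype(float)
    gc_c = gc - gc.mean()
    gc_sd = gc_c.std()
    if gc_sd == 0:
        raw = np.zeros(n_cells)
    else:
        gene_mean = np.asarray(X.mean(axis=0)).ravel()
        cross = np.asarray(X.T @ gc_c).ravel() / n_cells          # E[x*gc_c]
        sq = X.copy()
        sq.data = sq.data ** 2
        gene_var = np.asarray(sq.mean(axis=0)).ravel() - gene_mean ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(gene_var > 0, cross / (np.sqrt(gene_var) * gc_sd), 0.0)
        k = min(top_k, n_genes)
        if k < top_k:
            log.warning("stemness_score: only %d genes available (< top_k=%d)", n_genes, top_k)
        top = np.argsort(-corr, kind="stable")[:k]
        raw = np.asarray(X[:, top].mean(axis=1)).ravel()
    s = _diffuse(raw, knn_graph, smooth_alpha, smooth_steps)
    return _rank_scale(s)


def score_cells(adata, normalized, knn_graph, gene_sets: dict[str, list[str]],
                seed: int = 0, n_bins: int = 24, n_ctrl: int = 100,
                top_k: int = 200, smooth_alpha: float = 0.5,
                smooth_steps: int = 3) -> pd.DataFrame:
    """Bundle of per-cell scores: proliferation, S/G2M, phase, stemness, lineages.

    The proliferation and lineage scores that feed state assignment are
    kNN-diffusion smoothed (neighbors are overwhelmingly same-state, so this
    shrinks per-cell sampling noise around the decision thresholds without
    moving state-level means); the S/G2M scores behind the per-cell phase call
    stay raw.
    """
    gn = adata.var_names.to_numpy()

    def ms(set_name: str, salt: int, smooth: bool) -> np.ndarray:
        s = module_score(normalized, gn, gene_sets[set_name],
                         n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + salt)
        return _diffuse(s, knn_graph, smooth_alpha, smooth_steps) if smooth else s

    out = pd.DataFrame(index=adata.obs_names)
    out["s_score"] = ms("S", 1, smooth=False)
    out["g2m_score"] = ms("G2M", 2, smooth=False)
    out["proliferation"] = ms("proliferation", 3, smooth=True)
    out["phase"] = cycle_phase(out["s_score"].to_numpy(), out["g2m_score"].to_numpy())
    out["stemness"] = stemness_score(normalized, knn_graph, top_k=top_k,
                                     smooth_alpha=smooth_alpha,
                                     smooth_steps=smooth_steps)
    for key in gene_sets:
        if key.startswith("lineage:"):
            salt = 10 + sorted(gene_sets).index(key)
            out[key] = module_score(normalized, gn, gene_sets[key],
                                    n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + salt)
            out[key] = _diffuse(out[key].to_numpy(), knn_graph,
                                smooth_alpha, smooth_steps)
    return out


@dataclass
class StateAssignment:
    states: pd.Series          # per leukemia-like cell, one of the six states
    rationale: pd.DataFrame    # lineage argmax, proliferation, phase per cell


def assign_states(scores: pd.DataFrame, leukemia_like: pd.Series,
                  tau: float = 0.0) -> StateAssignment:
    """Deterministic six-state rule for leukemia-like cells.

    Lineage = argmax of the lineage program scores with fixed tie order
    stem > GMP > granulocyte > promono > mono.  Stem cells split into QSC
    (proliferation <= tau) vs PSP; granulocyte-lineage cells in S/G2M phase
    are PG, otherwise GMP.
    """
    leuk_cells = leukemia_like.index[leukemia_like == "leukemia-like"]
    if len(leuk_cells) == 0:
        raise ScoringError("no leukemia-like cells to assign")
    cols = [f"lineage:{l}" for l in LINEAGE_PRIORITY]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ScoringError(f"missing lineage scores: {missing}")
    sub = scores.loc[leuk_cells]
    lin_mat = sub[cols].to_numpy()
    lineage = np.asarray(LINEAGE_PRIORITY, dtype=object)[np.argmax(lin_mat, axis=1)]
    prolif = sub["proliferation"].to_numpy()
    phase = sub["phase"].to_numpy()
    state = np.empty(len(sub), dtype=object)
    is_stem = lineage == "stem"
    state[is_stem & (prolif <= tau)] = "QSC"
    state[is_stem & (prolif > tau)] = "PSP"
    is_gran = lineage == "granulocyte"
    state[is_gran & np.isin(phase, ("S", "G2M"))] = "PG"
    state[is_gran & (phase == "G1")] = "GMP"
    state[lineage == "GMP"] = "GMP"
    state[lineage == "promono"] = "promono"
    state[lineage == "mono"] = "mono"
    rationale = pd.DataFrame({"lineage": lineage, "proliferation": prolif, "phase": phase},
                             index=sub.index)
    return StateAssignment(states=pd.Series(state, index=sub.index, name="state"),
                           rationale=rationale)


def surface_markers(normalized, gene_names, states: pd.Series,
                    surface_list, min_logfc: float = 0.25,
                    max_fdr: float = 0.05, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest surface-marker tables per state.

    Rank-sum tests are restricted to genes on the provided surface list; kept
    markers need logFC >= ``min_logfc`` and BH-FDR <= ``max_fdr``.  Returns a
    long table (state, gene, logfc, p, fdr) sorted by state then descending
    logFC.
    """
    if len(surface_list) == 0:
        raise ScoringError("surface_list must be nonempty")
    gene_names = np.asarray(gene_names)
    surf_idx = np.flatnonzero(np.isin(gene_names, list(surface_list)))
    if surf_idx.size == 0:
        raise ScoringError("no surface-list gene present in the matrix")
    sub = normalized[:, surf_idx]
    sub_names = gene_names[surf_idx]
    states = states.astype(str)
    rows = []
    for st in sorted(states.unique()):
        mask_a = (states == st).to_numpy()
        mask_b = ~mask_a
        if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
            log.warning("surface_markers: state %s has <%d cells, skipped", st, min_cells)
            continue
        tab = rank_sum_table(sub, mask_a, mask_b, sub_names)
        keep = tab[(tab["logfc"] >= min_logfc) & (tab["fdr"] <= max_fdr)]
        keep = keep.sort_values("logfc", ascending=False)
        for gene, r in keep.iterrows():
            rows.append((st, gene, r["logfc"], r["p"], r["fdr"]))
    return pd.DataFrame(rows, columns=["state", "gene", "logfc", "p", "fdr"])


def _ssgsea_extremes(n: int, n_set: int, exponent: float) -> tuple[float, float]:
    """Running-sum totals when the set occupies the top / bottom of the ranking."""
    w = (np.arange(n, 0, -1, dtype=float)) ** exponent
    denom = (n_set / n) * w.sum()

    def total(in_mask: np.ndarray) -> float:
        w_in = np.where(in_mask, w, 0.0)
        cum_in = np.cumsum(w_in) / denom
        cum_out = np.cumsum(~in_mask) / (n - n_set)
        return float(np.sum(cum_in - cum_out))

    top = np.zeros(n, dtype=bool)
    top[:n_set] = True
    bottom = np.zeros(n, dtype=bool)
    bottom[-n_set:] = True
    return total(top), total(bottom)


def ssgsea_score(normalized, gene_names, gene_set,
                 exponent: float = 0.75) -> np.ndarray:
    """Single-sample enrichment score of a gene set, per cell.

    Genes are ranked by expression per cell; the score is the summed
    difference between the rank-weighted (``rank**exponent``) in-set ECDF and
    the uniform out-set ECDF, scaled by the range attained when the set sits
    wholly at the top vs wholly at the bottom of the ranking.
    """
    gene_names = np.asarray(gene_names)
    in_set = np.isin(gene_names, list(gene_set))
    n = len(gene_names)
    n_set = int(in_set.sum())
    if n_set < 2:
        raise ScoringError("gene set must have >= 2 genes present")
    if n_set == n:
        raise ScoringError("gene set covers all genes; out-set ECDF undefined")
    X = normalized.toarray() if sparse.issparse(normalized) else np.asarray(normalized)
    hi, lo = _ssgsea_extremes(n, n_set, exponent)
    w_pos = (np.arange(n, 0, -1, dtype=float)) ** exponent
    # the in-set running weight is normalized by its exchangeability
    # expectation (n_set/n of the total weight) rather than the realized set
    # weight, which centers a random set at exactly zero mean; the constant
    # `center` removes the residual rank-weight offset of the running sums
    denom = (n_set / n) * w_pos.sum()
    center = float(np.sum(np.cumsum(w_pos) / w_pos.sum() - np.arange(1, n + 1) / n))
    scores = np.empty(X.shape[0])
    for c in range(X.shape[0]):
        # stable descending order; ties resolved by gene index
        order = np.argsort(-X[c], kind="stable")
        mask = in_set[order]
        w_in = np.where(mask, w_pos, 0.0)
        cum_in = np.cumsum(w_in) / denom
        cum_out = np.cumsum(~mask) / (n - n_set)
        scores[c] = (np.sum(cum_in - cum_out) - center) / (hi - lo)
    return scores
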