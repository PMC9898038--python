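"""QC, normalization, PCA, kNN graph and high-resolution Leiden clustering.

The integration stage of the pipeline: cells from all samples are filtered,
library-size normalized, reduced to principal components over highly variable
genes, connected by a kNN graph and over-clustered with Leiden community
detection so that per-cluster condition composition can separate leukemia-like
from normal-like cells downstream.  The PCA projection parameters (HVG set,
per-gene center/scale, loadings) are retained so query cells from later
timepoints can be mapped into the same space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import linkage
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

log = logging.getLogger("lscape")

NORMALIZE_TARGET = 10_000.0
SCALE_CLIP = 10.0


class PreprocessError(ValueError):
    pass


@dataclass
class EmbeddingResult:
    """Reduced representation plus everything needed to project new cells."""

    normalized: sparse.csr_matrix      # cells x genes, log1p of CP10K
    hvg: np.ndarray                    # indices of highly variable genes
    gene_names: np.ndarray
    mu: np.ndarray                     # per-HVG mean of normalized values
    sigma: np.ndarray                  # per-HVG std (floored)
    components: np.ndarray             # d x n_hvg loadings
    pcs: np.ndarray                    # cells x d
    knn_indices: np.ndarray            # cells x k neighbor indices
    knn_distances: np.ndarray
    knn_graph: sparse.csr_matrix       # symmetrized unweighted adjacency
    embedding2d: np.ndarray            # cells x 2 (first two PCs)

    def project(self, normalized: sparse.spmatrix | np.ndarray,
                gene_names: np.ndarray) -> np.ndarray:
        """Project query cells (log-normalized, any gene order) into PC space."""
        name_to_col = {g: i for i, g in enumerate(gene_names)}
        cols, keep = [], []
        for j, g in enumerate(self.gene_names[self.hvg]):
            if g in name_to_col:
                cols.append(name_to_col[g])
                keep.append(j)
        if not cols:
            raise PreprocessError("query shares no HVGs with the reference")
        sub = normalized[:, cols]
        sub = sub.toarray() if sparse.issparse(sub) else np.asarray(sub)
        keep = np.asarray(keep)
        z = np.zeros((sub.shape[0], self.hvg.size))
        z[:, keep] = np.clip((sub - self.mu[keep]) / self.sigma[keep],
                             -SCALE_CLIP, SCALE_CLIP)
        return z @ self.components.T


@dataclass
class ClusterResult:
    labels: pd.Series                  # per-cell cluster id (int), indexed by cell
    resolution: float
    centroids: pd.DataFrame            # clusters x genes, mean log expression
    corr_tree: np.ndarray              # scipy linkage over centroid correlation


def qc_filter(adata: ad.AnnData, min_genes: int = 200, max_genes: int = 6000,
              max_mito_frac: float = 0.2, min_cells_per_gene: int = 3) -> ad.AnnData:
    """Remove low-quality cells and rarely expressed genes.

    Cells are dropped if their expressed-gene count falls outside
    ``[min_genes, max_genes]`` or their mitochondrial fraction (``MT-`` genes)
    exceeds ``max_mito_frac``; genes expressed in fewer than
    ``min_cells_per_gene`` cells are then removed.
    """
    X = sparse.csr_matrix(adata.X)
    n_genes = X.getnnz(axis=1)
    mt = np.asarray(adata.var_names.str.startswith("MT-"))
    tot = np.asarray(X.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(tot > 0,
                             np.asarray(X[:, mt].sum(axis=1)).ravel() / np.maximum(tot, 1),
                             0.0)
    pass_min = n_genes >= min_genes
    pass_max = n_genes <= max_genes
    pass_mito = mito_frac <= max_mito_frac
    keep = pass_min & pass_max & pass_mito
    log.info("qc_filter: %d/%d cells pass (min_genes drops %d, max_genes %d, mito %d)",
             keep.sum(), keep.size, (~pass_min).sum(), (~pass_max).sum(), (~pass_mito).sum())
    if keep.sum() == 0:
        rule = ("min_genes" if (~pass_min).all() else
                "max_genes" if (~pass_max).all() else "max_mito_frac")
        raise PreprocessError(f"qc_filter removed every cell (binding rule: {rule})")
    out = adata[keep].copy()
    gene_keep = sparse.csr_matrix(out.X).getnnz(axis=0) >= min_cells_per_gene
    log.info("qc_filter: %d/%d genes kept", gene_keep.sum(), gene_keep.size)
    return out[:, gene_keep].copy()


def normalize_log(adata: ad.AnnData) -> sparse.csr_matrix:
    """Library-size normalize to 10,000 counts per cell, then log1p.

    Returns a cells x genes sparse matrix; zeros stay exact zeros.
    """
    X = sparse.csr_matrix(adata.X, dtype=np.float64)
    tot = np.asarray(X.sum(axis=1)).ravel()
    if np.any(tot == 0):
        raise PreprocessError("zero-total cell encountered; run qc_filter first")
    scaled = sparse.diags(NORMALIZE_TARGET / tot) @ X
    scaled.data = np.log1p(scaled.data)
    return scaled.tocsr()


def _select_hvg(normalized: sparse.csr_matrix, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Highly variable genes by within-bin normalized dispersion of expm1 data."""
    n_cells, n_genes = normalized.shape
    lin = normalized.copy()
    lin.data = np.expm1(lin.data)
    mean = np.asarray(lin.mean(axis=0)).ravel()
    sq = lin.copy()
    sq.data = sq.data ** 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros(n_genes)
    for b in bins:
        if b.size == 0:
            continue
        d = disp[b]
        sd = d.std()
        z[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    top = np.argsort(-z, kind="stable")[: min(n_hvg, n_genes)]
    return np.sort(top)


def reduce_and_graph(adata: ad.AnnData, normalized: sparse.csr_matrix,
                     n_hvg: int = 1000, d: int = 30, k: int = 15,
                     seed: int = 0, pcs: np.ndarray | None = None) -> EmbeddingResult:
    """HVG selection, scaling, PCA and kNN graph.

    ``pcs`` may supply externally integrated coordinates; HVG/scaling/loadings
    are still computed so projection of query cells remains available.
    """
    n_cells, n_genes = normalized.shape
    if n_hvg > n_genes:
        raise PreprocessError("n_hvg exceeds gene count")
    if d >= n_cells:
        raise PreprocessError("d must be smaller than the number of cells")
    hvg = _select_hvg(normalized, n_hvg)
    sub = normalized[:, hvg].toarray()
    mu = sub.mean(axis=0)
    sigma = sub.std(axis=0)
    sigma[sigma == 0] = 1.0
    z = np.clip((sub - mu) / sigma, -SCALE_CLIP, SCALE_CLIP)
    d_eff = min(d, min(z.shape) - 1)
    U, S, Vt = randomized_svd(z, n_components=d_eff, random_state=seed)
    # deterministic sign convention: largest-magnitude loading positive
    signs = np.sign(Vt[np.arange(d_eff), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    computed_pcs = (z @ Vt.T)
    use_pcs = computed_pcs if pcs is None else np.asarray(pcs)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_cells)).fit(use_pcs)
    dist, idx = nn.kneighbors(use_pcs)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n_cells), idx.shape[1])
    adj = sparse.csr_matrix((np.ones(rows.size), (rows, idx.ravel())),
                            shape=(n_cells, n_cells))
    adj = adj.maximum(adj.T)
    return EmbeddingResult(
        normalized=normalized, hvg=hvg, gene_names=adata.var_names.to_numpy(),
        mu=mu, sigma=sigma, components=Vt, pcs=use_pcs,
        knn_indices=idx, knn_distances=dist, knn_graph=adj,
        embedding2d=use_pcs[:, :2].copy(),
    )


def cluster_cells(adata: ad.AnnData, emb: EmbeddingResult,
                  resolution: float = 3.0, seed: int = 0) -> ClusterResult:
    """Leiden community detection on the kNN graph, plus centroid correlation tree."""
    adj = sparse.coo_matrix(emb.knn_graph)
    if adj.nnz == 0:
        raise PreprocessError("empty kNN graph")
    mask = adj.row < adj.col
    g = igraph.Graph(n=adj.shape[0],
                     edges=list(zip(adj.row[mask].tolist(), adj.col[mask].tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    labels = np.asarray(part.membership)
    label_s = pd.Series(labels, index=adata.obs_names, name="cluster")
    norm = emb.normalized
    n_clusters = labels.max() + 1
    ind = sparse.csr_matrix(
        (np.ones(labels.size), (labels, np.arange(labels.size))),
        shape=(n_clusters, labels.size),
    )
    sizes = np.asarray(ind.sum(axis=1)).ravel()
    centroids = np.asarray((ind @ norm).todense()) / sizes[:, None]
    cent_df = pd.DataFrame(centroids, index=np.arange(n_clusters), columns=adata.var_names)
    tree = None
    if n_clusters >= 2:
        corr = np.corrcoef(centroids)
        corr = np.nan_to_num(corr, nan=0.0)
        dist_vec = []
        for i in range(n_clusters):
            for j in range(i + 1, n_clusters):
                dist_vec.append(1.0 - corr[i, j])
        tree = linkage(np.asarray(dist_vec), method="average")
    return ClusterResult(labels=label_s, resolution=resolution,
                         centroids=cent_df, corr_tree=tree)
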