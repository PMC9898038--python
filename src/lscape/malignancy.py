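"""Leukemia-like vs normal-like cell calls and the condition density-ratio map.

Because AML blasts and healthy hematopoietic cells co-occupy the same
differentiation hierarchy, malignancy is inferred from cluster composition: a
cluster overwhelmingly populated by AML-patient cells has no healthy
counterpart and is called leukemia-like.  Healthy-control cells are never
labeled leukemia-like, whatever cluster they fall in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ClusterResult


class MalignancyError(ValueError):
    pass


@dataclass
class MalignancyCall:
    per_cluster: pd.DataFrame      # n_cells, n_aml_cells, aml_fraction, call
    per_cell: pd.Series            # "leukemia-like" / "normal-like", indexed by cell
    global_aml_fraction: float
    per_patient_fraction: pd.Series  # predicted leukemia-like share of each AML patient's cells


@dataclass
class DensityGrid:
    bins: int
    epsilon: float
    counts_aml: np.ndarray         # B x B
    counts_hc: np.ndarray
    log2_ratio: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def classify_clusters(cr: ClusterResult, meta: pd.DataFrame,
                      theta_high: float = 0.9,
                      mode: str = "threshold",
                      enrichment_rho: float = 2.0) -> MalignancyCall:
    """Call clusters leukemia-like from their AML-cell fraction.

    ``meta`` must carry ``condition`` (AML/HC) and ``sample`` columns aligned
    with the clustering.  In the default ``threshold`` mode a cluster is
    leukemia-like iff its AML fraction f_k >= ``theta_high``; the alternative
    ``enrichment`` mode instead requires f_k / global AML fraction >=
    ``enrichment_rho``.  AML-patient cells inherit their cluster's call; HC
    cells are always normal-like.
    """
    if "condition" not in meta.columns:
        raise MalignancyError("meta must contain a 'condition' column")
    cond = meta.loc[cr.labels.index, "condition"]
    is_aml = (cond == "AML").to_numpy()
    if is_aml.sum() == 0:
        raise MalignancyError("no AML cells present")
    labels = cr.labels.to_numpy()
    clusters = np.unique(labels)
    n_cells = np.array([(labels == c).sum() for c in clusters])
    n_aml = np.array([(is_aml & (labels == c)).sum() for c in clusters])
    frac = n_aml / n_cells
    global_frac = is_aml.mean()
    if mode == "threshold":
        leuk = frac >= theta_high
    elif mode == "enrichment":
        leuk = frac / global_frac >= enrichment_rho
    else:
        raise MalignancyError(f"unknown mode {mode!r}")
    per_cluster = pd.DataFrame({
        "n_cells": n_cells, "n_aml_cells": n_aml, "aml_fraction": frac,
        "call": np.where(leuk, "leukemia-like", "normal-like"),
    }, index=pd.Index(clusters, name="cluster"))
    cluster_call = per_cluster["call"].reindex(labels).to_numpy()
    per_cell = pd.Series(
        np.where(is_aml & (cluster_call == "leukemia-like"), "leukemia-like", "normal-like"),
        index=cr.labels.index, name="malignancy",
    )
    aml_meta = meta.loc[cr.labels.index][is_aml]
    leuk_cell = per_cell[is_aml] == "leukemia-like"
    per_patient = leuk_cell.groupby(aml_meta["sample"].to_numpy()).mean() * 100.0
    return MalignancyCall(per_cluster=per_cluster, per_cell=per_cell,
                          global_aml_fraction=float(global_frac),
                          per_patient_fraction=per_patient.rename("leukemia_like_pct"))


def density_ratio_map(embedding2d: np.ndarray, condition: pd.Series | np.ndarray,
                      bins: int = 400, epsilon: float | None = None) -> DensityGrid:
    """log2 AML/HC density ratio over a square binning of a 2D embedding.

    Each condition's bin counts are normalized to sum to 1; the ratio is
    ``log2((d_AML + eps) / (d_HC + eps))`` with ``eps`` defaulting to
    ``1 / max(condition totals)``.
    """
    if bins < 2:
        raise MalignancyError("need at least 2 bins per axis")
    cond = np.asarray(condition)
    xy = np.asarray(embedding2d, dtype=float)
    aml, hc = xy[cond == "AML"], xy[cond == "HC"]
    if len(aml) == 0 or len(hc) == 0:
        raise MalignancyError("need at least one cell per condition")
    x_edges = np.linspace(xy[:, 0].min(), xy[:, 0].max(), bins + 1)
    y_edges = np.linspace(xy[:, 1].min(), xy[:, 1].max(), bins + 1)
    c_aml, _, _ = np.histogram2d(aml[:, 0], aml[:, 1], bins=[x_edges, y_edges])
    c_hc, _, _ = np.histogram2d(hc[:, 0], hc[:, 1], bins=[x_edges, y_edges])
    if epsilon is None:
        epsilon = 1.0 / max(len(aml), len(hc))
    d_aml = c_aml / len(aml)
    d_hc = c_hc / len(hc)
    ratio = np.log2((d_aml + epsilon) / (d_hc + epsilon))
    return DensityGrid(bins=bins, epsilon=float(epsilon), counts_aml=c_aml,
                       counts_hc=c_hc, log2_ratio=ratio,
                       x_edges=x_edges, y_edges=y_edges)
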