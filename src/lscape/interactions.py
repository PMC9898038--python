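"""Ligand-receptor interaction scoring between cellular states.

For each (ligand, receptor, sender state, receiver state) combination the
score is the mean-of-means: (mean ligand expression in the sender + mean
receptor expression in the receiver) / 2, evaluated only when both genes are
expressed in at least ``min_frac`` of the respective cells.  Significance
comes from an empirical null built by permuting state labels across all cells,
with an add-one correction so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


class InteractionError(ValueError):
    pass


@dataclass
class LRResult:
    table: pd.DataFrame   # ligand, receptor, sender, receiver, mean_score,
    #                       expr_frac_sender, expr_frac_receiver, p_perm, n_perm
    n_perm: int


def score_lr(normalized, gene_names, states: pd.Series,
             pairs: list[tuple[str, str]], min_frac: float = 0.1,
             n_perm: int = 1000, seed: int = 0,
             sender_states: list[str] | None = None,
             receiver_states: list[str] | None = None) -> LRResult:
    """Permutation-tested ligand-receptor scores for all state combinations.

    ``states`` gives each cell's state label; combinations whose expressing
    fraction falls below ``min_frac`` on either side are filtered out (no p
    assigned).  p_perm = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise InteractionError("n_perm < 100 gives unstable p-values")
    if not pairs:
        raise InteractionError("pair table is empty")
    X = sparse.csr_matrix(normalized)
    gene_names = np.asarray(gene_names)
    col_of = {g: i for i, g in enumerate(gene_names)}
    states = states.astype(str)
    labels = states.to_numpy()
    uniq = sorted(states.unique())
    senders = list(sender_states or uniq)
    receivers = list(receiver_states or uniq)
    genes_needed = sorted({g for p in pairs for g in p if g in col_of})
    sub = X[:, [col_of[g] for g in genes_needed]].toarray()
    gcol = {g: j for j, g in enumerate(genes_needed)}

    def group_stats(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """states x genes mean expression and expressing fraction."""
        means = np.empty((len(uniq), sub.shape[1]))
        fracs = np.empty_like(means)
        for i, st in enumerate(uniq):
            m = lab == st
            means[i] = sub[m].mean(axis=0)
            fracs[i] = (sub[m] > 0).mean(axis=0)
        return means, fracs

    obs_mean, obs_frac = group_stats(labels)
    srow = {st: uniq.index(st) for st in uniq}

    combos = []  # (ligand, receptor, sender, receiver, score, f_s, f_r)
    for lig, rec in pairs:
        if lig not in gcol or rec not in gcol:
            continue
        for s in senders:
            for r in receivers:
                f_s = obs_frac[srow[s], gcol[lig]]
                f_r = obs_frac[srow[r], gcol[rec]]
                if f_s < min_frac or f_r < min_frac:
                    continue
                score = 0.5 * (obs_mean[srow[s], gcol[lig]] + obs_mean[srow[r], gcol[rec]])
                combos.append((lig, rec, s, r, score, f_s, f_r))
    if not combos:
        return LRResult(table=pd.DataFrame(
            columns=["ligand", "receptor", "sender", "receiver", "mean_score",
                     "expr_frac_sender", "expr_frac_receiver", "p_perm", "n_perm"]),
            n_perm=n_perm)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(combos), dtype=int)
    obs_scores = np.array([c[4] for c in combos])
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        p_mean, _ = group_stats(perm)
        null = np.array([
            0.5 * (p_mean[srow[s], gcol[lig]] + p_mean[srow[r], gcol[rec]])
            for (lig, rec, s, r, *_rest) in combos
        ])
        exceed += null >= obs_scores
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    table = pd.DataFrame(combos, columns=["ligand", "receptor", "sender", "receiver",
                                          "mean_score", "expr_frac_sender",
                                          "expr_frac_receiver"])
    table["p_perm"] = pvals
    table["n_perm"] = n_perm
    return LRResult(table=table, n_perm=n_perm)
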