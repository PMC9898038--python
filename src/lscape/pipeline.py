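"""End-to-end orchestration: simulate -> preprocess -> cluster -> malignancy ->
states -> ITH -> optional survival / deconvolution / longitudinal / interactions.

A single global seed fans out to per-stage seeds by hashing the stage name
(CRC-32 of the name XOR the global seed, reduced mod 2^31), so enabling or
disabling optional stages never changes the results of earlier stages.  The
run emits a machine-readable JSON report of all per-stage outputs; the report
carries no timestamps, so a rerun with the same seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconv, heterogeneity, interactions, io, longitudinal, malignancy
from . import preprocess, scoring, synthetic

log = logging.getLogger("lscape")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "paths": {"input": None, "bulk": None, "survival": None, "out": None},
    "stages": {"simulate": True, "survival": True, "deconvolve": True,
               "longitudinal": True, "interactions": True},
    "simulate": {"n_genes": 2000, "n_patients_aml": 7, "n_patients_hc": 20,
                 "cells_per_sample": 500},
    "qc": {"min_genes": 200, "max_genes": 6000, "max_mito_frac": 0.2},
    "reduce": {"n_hvg": 1000, "d": 30, "k": 15},
    "cluster": {"resolution": 3.0},
    "malignancy": {"theta_high": 0.9, "mode": "threshold", "grid_bins": 400},
    "states": {"tau": 0.0, "n_bins": 24, "n_ctrl": 100, "top_k": 200},
    "markers": {"min_logfc": 0.25, "max_fdr": 0.05},
    "ith": {"normalized": False},
    "survival": {"beta_ith": 0.6931471805599453, "beta_qsc": 0.0,
                 "baseline_rate": 0.002, "censor_rate": 0.001},
    "deconvolve": {"top_m": 50, "max_fdr": 0.05, "n_mixtures": 50, "noise_sd": 0.1},
    "longitudinal": {"k": 15, "lambda": 0.5, "cells_per_timepoint": 2000},
    "interactions": {"min_frac": 0.1, "n_perm": 1000},
}


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32(stage) XOR global seed, mod 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2 ** 31)


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    cfg = deepcopy(DEFAULT_CONFIG)
    for key, val in (user or {}).items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown config key {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = val
    return cfg


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: dict | None = None) -> dict:
    """Run the whole pipeline and return the report dictionary.

    With ``stages.simulate`` the cohort comes from the bundled generator;
    otherwise ``paths.input`` must point at an MTX trio.  If ``paths.out`` is
    set, the report, resolved config and key tables are written there.
    """
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "stages": {}}

    # ------------------------------------------------------------- input
    if cfg["stages"]["simulate"]:
        gen_cfg = synthetic.default_config(seed=stage_seed(seed, "simulate"),
                                           **cfg["simulate"])
        adata, truth = synthetic.simulate_cohort(gen_cfg)
    else:
        if not cfg["paths"]["input"]:
            raise ConfigError("stages.simulate is off but paths.input is unset")
        adata = io.read_cellmatrix(cfg["paths"]["input"])
        gen_cfg, truth = None, None
    report["stages"]["input"] = {"n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars)}

    # -------------------------------------------------- preprocess + cluster
    adata = preprocess.qc_filter(adata, **cfg["qc"])
    norm = preprocess.normalize_log(adata)
    emb = preprocess.reduce_and_graph(adata, norm, seed=stage_seed(seed, "reduce"),
                                      **cfg["reduce"])
    cr = preprocess.cluster_cells(adata, emb, resolution=cfg["cluster"]["resolution"],
                                  seed=stage_seed(seed, "cluster"))
    report["stages"]["cluster"] = {
        "n_cells_after_qc": int(adata.n_obs),
        "n_clusters": int(cr.labels.nunique()),
        "resolution": cfg["cluster"]["resolution"],
    }

    # ------------------------------------------------------------ malignancy
    mal = malignancy.classify_clusters(cr, adata.obs,
                                       theta_high=cfg["malignancy"]["theta_high"],
                                       mode=cfg["malignancy"]["mode"])
    grid = malignancy.density_ratio_map(emb.embedding2d, adata.obs["condition"],
                                        bins=cfg["malignancy"]["grid_bins"])
    report["stages"]["malignancy"] = {
        "n_leukemia_like_clusters": int((mal.per_cluster["call"] == "leukemia-like").sum()),
        "global_aml_fraction": mal.global_aml_fraction,
        "per_patient_leukemia_pct": mal.per_patient_fraction.round(4).to_dict(),
        "grid_occupied_bins": int(((grid.counts_aml + grid.counts_hc) > 0).sum()),
    }

    # ---------------------------------------------------------- state scores
    gene_sets = adata.uns.get("gene_sets")
    if gene_sets is None:
        raise ConfigError("no gene_sets annotation available for state scoring")
    scores = scoring.score_cells(adata, norm, emb.knn_graph, gene_sets,
                                 seed=stage_seed(seed, "states"),
                                 n_bins=cfg["states"]["n_bins"],
                                 n_ctrl=cfg["states"]["n_ctrl"],
                                 top_k=cfg["states"]["top_k"])
    assign = scoring.assign_states(scores, mal.per_cell, tau=cfg["states"]["tau"])
    surface = adata.uns.get("surface_genes", [])
    marker_table = pd.DataFrame()
    if len(surface):
        leuk_idx = assign.states.index
        leuk_mask = adata.obs_names.isin(leuk_idx)
        marker_table = scoring.surface_markers(
            norm[leuk_mask], adata.var_names.to_numpy(),
            assign.states.loc[adata.obs_names[leuk_mask]], surface,
            min_logfc=cfg["markers"]["min_logfc"], max_fdr=cfg["markers"]["max_fdr"])
    report["stages"]["states"] = {
        "n_leukemia_like_cells": int(len(assign.states)),
        "state_counts": assign.states.value_counts().to_dict(),
        "n_surface_markers": int(len(marker_table)),
    }

    # -------------------------------------------------------- composition/ITH
    samples = adata.obs["sample"]
    records = heterogeneity.composition(assign.states, samples,
                                        normalized_entropy=cfg["ith"]["normalized"])
    comp = heterogeneity.composition_frame(records)
    report["stages"]["ith"] = {
        "composition": comp.round(6).to_dict(orient="index"),
    }

    # --------------------------------------------------------------- survival
    if cfg["stages"]["survival"]:
        if cfg["paths"]["survival"]:
            surv = io.read_survival(cfg["paths"]["survival"]).join(comp["ITH"], how="inner")
        else:
            betas = {"ITH": cfg["survival"]["beta_ith"], "QSC": cfg["survival"]["beta_qsc"]}
            surv = synthetic.simulate_survival(
                comp, betas=betas,
                baseline_rate=cfg["survival"]["baseline_rate"],
                censor_rate=cfg["survival"]["censor_rate"],
                seed=stage_seed(seed, "survival"))
            surv = surv.join(comp["ITH"])
        try:
            surv["group"] = heterogeneity.median_split(surv["ITH"])
            chi2, p = heterogeneity.logrank_test(surv)
            report["stages"]["survival"] = {"logrank_chi2": chi2, "logrank_p": p,
                                            "n_samples": int(len(surv))}
        except heterogeneity.HeterogeneityError as exc:
            report["stages"]["survival"] = {"skipped": str(exc)}

    # ------------------------------------------------------------ deconvolve
    if cfg["stages"]["deconvolve"]:
        leuk_mask = adata.obs_names.isin(assign.states.index)
        sig = deconv.build_signature(norm[leuk_mask], adata.var_names.to_numpy(),
                                     assign.states.loc[adata.obs_names[leuk_mask]],
                                     top_m=cfg["deconvolve"]["top_m"],
                                     max_fdr=cfg["deconvolve"]["max_fdr"])
        if cfg["paths"]["bulk"]:
            bulk = io.read_bulk(cfg["paths"]["bulk"])
            res = deconv.deconvolve(bulk, sig)
            report["stages"]["deconvolve"] = {
                "proportions": res.proportions.round(6).to_dict(orient="index")}
        else:
            rng = np.random.default_rng(stage_seed(seed, "deconvolve"))
            n_mix = cfg["deconvolve"]["n_mixtures"]
            states = list(sig.matrix.columns)
            true_p = rng.dirichlet(np.ones(len(states)), size=n_mix)
            profiles = sig.matrix.T  # states x genes
            bulk = synthetic.simulate_bulk_mixtures(
                profiles, pd.DataFrame(true_p, columns=states,
                                       index=[f"mix{i:03d}" for i in range(n_mix)]),
                noise_sd=cfg["deconvolve"]["noise_sd"],
                seed=stage_seed(seed, "mixtures"))
            res = deconv.deconvolve(bulk, sig)
            est = res.proportions[states].to_numpy()
            rmse = float(np.sqrt(np.mean((est - true_p) ** 2)))
            report["stages"]["deconvolve"] = {
                "n_signature_genes": int(len(sig.matrix)),
                "self_mixture_rmse": rmse,
            }

    # ----------------------------------------------------------- longitudinal
    if cfg["stages"]["longitudinal"] and gen_cfg is not None:
        lam = float(cfg["longitudinal"]["lambda"])
        lcfg = synthetic.default_config(seed=stage_seed(seed, "longitudinal"),
                                        **cfg["simulate"])
        pre, post, ltruth = synthetic.simulate_longitudinal(
            lcfg, lam, cells_per_timepoint=cfg["longitudinal"]["cells_per_timepoint"])
        pre_q = preprocess.qc_filter(pre, **cfg["qc"])
        pre_norm = preprocess.normalize_log(pre_q)
        pre_emb = preprocess.reduce_and_graph(pre_q, pre_norm,
                                              seed=stage_seed(seed, "longitudinal"),
                                              **cfg["reduce"])
        pre_labels = pre_q.obs["true_state"] if "true_state" in pre_q.obs else None
        if pre_labels is None:
            report["stages"]["longitudinal"] = {"skipped": "no reference labels"}
        else:
            post_q = preprocess.qc_filter(post, **cfg["qc"])
            transfer = longitudinal.transfer_labels(
                pre_labels.astype(str), pre_q.obs_names.to_numpy(), pre_emb, post_q,
                k=cfg["longitudinal"]["k"])
            shift = longitudinal.composition_shift(pre_labels.astype(str), transfer.labels)
            post_norm = preprocess.normalize_log(post_q)
            de = longitudinal.state_de(
                pre_norm[(pre_labels == "PSP").to_numpy()],
                post_norm[(transfer.labels == "PSP").to_numpy()],
                pre_q.var_names.to_numpy(), state="PSP",
                min_logfc=cfg["markers"]["min_logfc"], max_fdr=cfg["markers"]["max_fdr"])
            axis = longitudinal.state_de(
                pre_norm[(pre_labels == "PSP").to_numpy()],
                pre_norm[(pre_labels == "QSC").to_numpy()],
                pre_q.var_names.to_numpy(), state="QSC-vs-PSP")
            rp = longitudinal.reprogramming_index(
                pre_norm[(pre_labels == "QSC").to_numpy()],
                pre_norm[(pre_labels == "PSP").to_numpy()],
                post_norm[(transfer.labels == "PSP").to_numpy()],
                pre_q.var_names.to_numpy(), list(axis.index))
            report["stages"]["longitudinal"] = {
                "lambda": lam,
                "reprogramming_index": rp.r,
                "proportion_shift": shift.proportions.round(6).to_dict(orient="index"),
                "n_de_genes_psp": int(len(de)),
            }

    # ----------------------------------------------------------- interactions
    if cfg["stages"]["interactions"]:
        pairs = [tuple(p) for p in adata.uns.get("lr_pairs", [])]
        if pairs:
            leuk_and_state = assign.states
            cells = adata.obs_names.isin(leuk_and_state.index)
            lr = interactions.score_lr(
                norm[cells], adata.var_names.to_numpy(),
                leuk_and_state.loc[adata.obs_names[cells]], pairs,
                min_frac=cfg["interactions"]["min_frac"],
                n_perm=cfg["interactions"]["n_perm"],
                seed=stage_seed(seed, "interactions"))
            top = lr.table.sort_values(["p_perm", "mean_score"],
                                       ascending=[True, False]).head(10)
            report["stages"]["interactions"] = {
                "n_combinations": int(len(lr.table)),
                "top": top.round(6).to_dict(orient="records"),
            }

    report = _round_floats(report)

    out = cfg["paths"]["out"]
    if out:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))
        cr.labels.to_csv(outdir / "clusters.tsv", sep="\t")
        comp.to_csv(outdir / "composition.csv")
        assign.states.to_csv(outdir / "states.tsv", sep="\t")
        if len(marker_table):
            marker_table.to_csv(outdir / "surface_markers.tsv", sep="\t", index=False)
    return report
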