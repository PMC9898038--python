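"""Ground-truthed synthetic bone-marrow cohorts for the leukemia landscape pipeline.

The generator emulates a two-condition (healthy control vs relapsed/refractory
AML) bone-marrow single-cell cohort: normal hematopoietic lineages present in
both conditions, and six leukemia-like cellular states (QSC, PSP, GMP, PG,
promono, mono) exclusive to AML samples.  Counts follow a negative-binomial
(gamma-Poisson) model with log-normal library sizes, multiplicative per-patient
effects and optional extra dropout.  Every cell's state, condition, patient,
malignancy flag and cell-cycle phase are recorded as ground truth, as are
per-sample state compositions, so downstream classifiers and scores can be
validated against planted labels.

Stemness is planted as an expressed-gene-richness gradient: stem-like states
activate more low-level gene programs than differentiated states, while the
library-size distribution is shared across states so transcriptional diversity
is not confounded with sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

LEUKEMIA_STATES = ("QSC", "PSP", "GMP", "PG", "promono", "mono")

# fixed tie-break / reporting order for the six leukemia states
STATE_ORDER = list(LEUKEMIA_STATES)


class GeneratorError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class StateSpec:
    """One cellular state (leukemia-like or normal lineage) of the cohort.

    ``diversity_rank`` is the number of low-level gene programs the state
    expresses (higher for stem-like states), which realizes the planted
    expressed-gene-richness / stemness ordering.
    """

    name: str
    marker_genes: np.ndarray
    marker_log_effect: float
    cycling: bool
    diversity_rank: int
    surface_flagged_markers: np.ndarray
    prop_hc: float
    prop_aml: float
    is_leukemia: bool


@dataclass
class GeneratorConfig:
    n_genes: int
    states: list[StateSpec]
    n_patients_aml: int = 7
    n_patients_hc: int = 20
    cells_per_sample: int = 500
    patient_effect_sd: float = 0.15
    dispersion: float = 2.0
    libsize_log_mean: float = math.log(2500.0)
    libsize_log_sd: float = 0.25
    dropout_extra: float = 0.05
    seed: int = 0
    # gene annotation (index sets into 0..n_genes-1)
    gene_names: list[str] = field(default_factory=list)
    mt_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    stem_program: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    s_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    g2m_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    diversity_programs: list[np.ndarray] = field(default_factory=list)
    # effect sizes (natural-log scale)
    stem_log_effect: float = 1.0
    cycle_log_effect: float = 1.2
    diversity_log_effect: float = 1.5
    # how strongly differentiated states concentrate expression in their
    # marker program (scaled by 1 - diversity_rank/n_programs); this is what
    # makes low-diversity states express fewer distinct genes at fixed depth
    concentration_log_effect: float = 2.0
    # per-sample composition jitter: Dirichlet concentration, None = exact baseline
    composition_concentration: float | None = 150.0
    # mitochondrial fraction model (Beta by mean/concentration), per condition
    mito_frac_mean_hc: float = 0.05
    mito_frac_mean_aml: float = 0.05
    mito_frac_conc: float = 30.0
    mito_high_frac: float = 0.0
    mito_high_level: float = 0.5

    def validate(self) -> None:
        if self.n_genes < 1 or self.cells_per_sample < 1:
            raise GeneratorError("n_genes and cells_per_sample must be >= 1")
        if self.n_patients_aml < 1 or self.n_patients_hc < 0:
            raise GeneratorError("need at least one AML patient")
        if not self.states:
            raise GeneratorError("states must be nonempty")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise GeneratorError("state names must be unique")
        if self.dispersion <= 0:
            raise GeneratorError("dispersion must be positive")
        if self.patient_effect_sd < 0:
            raise GeneratorError("patient_effect_sd must be nonnegative")
        for p in (self.dropout_extra, self.mito_high_frac):
            if not 0.0 <= p <= 1.0:
                raise GeneratorError("probabilities must lie in [0, 1]")
        seen: set[int] = set()
        for s in self.states:
            idx = np.asarray(s.marker_genes)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise GeneratorError(
                    f"state {s.name!r}: marker indices exceed n_genes={self.n_genes}"
                )
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise GeneratorError(f"marker sets not disjoint (gene {sorted(overlap)[:3]})")
            seen.update(idx.tolist())
            if s.name == "QSC" and s.cycling:
                raise GeneratorError("QSC must be non-cycling")
            if s.name in ("PSP", "PG") and not s.cycling:
                raise GeneratorError(f"{s.name} must be cycling")
        for attr, tot in (("prop_hc", sum(s.prop_hc for s in self.states)),
                          ("prop_aml", sum(s.prop_aml for s in self.states))):
            if abs(tot - 1.0) > 1e-8:
                raise GeneratorError(f"{attr} proportions must sum to 1 (got {tot})")


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated cohort."""

    cells: pd.DataFrame              # per-cell: sample, patient, condition, state, malignant, phase
    sample_composition: pd.DataFrame  # AML samples x six states, fractions among leukemia cells
    sample_leukemia_fraction: pd.Series
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# default cohort layout
# ---------------------------------------------------------------------------

def default_config(
    n_genes: int = 2000,
    n_patients_aml: int = 7,
    n_patients_hc: int = 20,
    cells_per_sample: int = 500,
    markers_per_state: int = 40,
    program_size: int = 30,
    cycle_size: int = 40,
    n_diversity_programs: int = 10,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """Standard two-condition bone-marrow cohort with six leukemia states.

    Gene layout (all index blocks disjoint): 10 mitochondrial genes named
    ``MT-*``; per-state marker blocks (named surface markers CD52/LGALS1/CD47
    inside the QSC block and SIGLEC10/SIRPA/CD14 inside the mono block); a
    shared stem program (CD99, ITGA4, ...) expressed by both QSC and PSP; S and
    G2M cell-cycle programs; a pool of low-level diversity programs realizing
    the stemness gradient; the remainder is unstructured background.
    """
    n_mt = 10
    state_names = list(LEUKEMIA_STATES) + ["HSC_normal", "Erythroid", "Tcell", "Bcell"]
    need = (n_mt + markers_per_state * len(state_names) + program_size
            + 2 * cycle_size + n_diversity_programs * program_size)
    if n_genes < need + 50:
        raise GeneratorError(f"n_genes={n_genes} too small for default layout (need >= {need + 50})")

    names = [f"G{i:05d}" for i in range(n_genes)]
    for i in range(n_mt):
        names[i] = f"MT-{i + 1}"
    pos = n_mt
    marker_idx: dict[str, np.ndarray] = {}
    for sname in state_names:
        marker_idx[sname] = np.arange(pos, pos + markers_per_state)
        pos += markers_per_state
    stem_program = np.arange(pos, pos + program_size)
    pos += program_size
    s_genes = np.arange(pos, pos + cycle_size)
    pos += cycle_size
    g2m_genes = np.arange(pos, pos + cycle_size)
    pos += cycle_size
    diversity_programs = []
    for _ in range(n_diversity_programs):
        diversity_programs.append(np.arange(pos, pos + program_size))
        pos += program_size

    # named genes the downstream analyses look for
    for gi, nm in zip(marker_idx["QSC"][:3], ("CD52", "LGALS1", "CD47")):
        names[gi] = nm
    for gi, nm in zip(marker_idx["mono"][:3], ("SIGLEC10", "SIRPA", "CD14")):
        names[gi] = nm
    for gi, nm in zip(stem_program[:2], ("CD99", "ITGA4")):
        names[gi] = nm

    # baseline proportions: leukemia states exclusive to AML; normal lineages shared
    prop_aml = {"QSC": 0.07, "PSP": 0.14, "GMP": 0.14, "PG": 0.105,
                "promono": 0.14, "mono": 0.105,
                "HSC_normal": 0.06, "Erythroid": 0.09, "Tcell": 0.09, "Bcell": 0.06}
    prop_hc = {"QSC": 0.0, "PSP": 0.0, "GMP": 0.0, "PG": 0.0, "promono": 0.0, "mono": 0.0,
               "HSC_normal": 0.20, "Erythroid": 0.30, "Tcell": 0.30, "Bcell": 0.20}
    cycling = {"PSP", "PG"}
    diversity_rank = {"QSC": 9, "PSP": 9, "GMP": 6, "PG": 6, "promono": 4, "mono": 2,
                      "HSC_normal": 8, "Erythroid": 3, "Tcell": 3, "Bcell": 3}

    states = []
    n_surf = min(6, markers_per_state)
    for sname in state_names:
        states.append(StateSpec(
            name=sname,
            marker_genes=marker_idx[sname],
            marker_log_effect=1.2,
            cycling=sname in cycling,
            diversity_rank=diversity_rank[sname],
            surface_flagged_markers=marker_idx[sname][:n_surf],
            prop_hc=prop_hc[sname],
            prop_aml=prop_aml[sname],
            is_leukemia=sname in LEUKEMIA_STATES,
        ))

    cfg = GeneratorConfig(
        n_genes=n_genes,
        states=states,
        n_patients_aml=n_patients_aml,
        n_patients_hc=n_patients_hc,
        cells_per_sample=cells_per_sample,
        seed=seed,
        gene_names=names,
        mt_genes=np.arange(n_mt),
        stem_program=stem_program,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        diversity_programs=diversity_programs,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def gene_sets(config: GeneratorConfig) -> dict[str, list[str]]:
    """Bundled gene sets (S/G2M/proliferation and lineage programs) by gene name."""
    nm = np.asarray(config.gene_names)
    by_state = {s.name: s.marker_genes for s in config.states}
    sets = {
        "S": nm[config.s_genes].tolist(),
        "G2M": nm[config.g2m_genes].tolist(),
        "proliferation": nm[np.concatenate([config.s_genes, config.g2m_genes])].tolist(),
        "lineage:stem": nm[config.stem_program].tolist(),
    }
    for lineage, state in (("GMP", "GMP"), ("granulocyte", "PG"),
                           ("promono", "promono"), ("mono", "mono")):
        if state in by_state:
            sets[f"lineage:{lineage}"] = nm[by_state[state]].tolist()
    return sets


def surface_genes(config: GeneratorConfig) -> list[str]:
    nm = np.asarray(config.gene_names)
    out: list[str] = []
    for s in config.states:
        if s.is_leukemia:
            out.extend(nm[s.surface_flagged_markers].tolist())
    out.extend(nm[config.stem_program[:2]].tolist())  # CD99, ITGA4
    return sorted(set(out))


def lr_pairs() -> list[tuple[str, str]]:
    """Default ligand-receptor table (CD52-SIGLEC10 and CD47-SIRPA)."""
    return [("CD52", "SIGLEC10"), ("CD47", "SIRPA")]


# ---------------------------------------------------------------------------
# expression model
# ---------------------------------------------------------------------------

def _base_log_means(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline log relative expression (drawn once per config seed)."""
    return rng.normal(0.0, 1.0, config.n_genes)


def _state_log_profile(config: GeneratorConfig, beta: np.ndarray, spec: StateSpec) -> np.ndarray:
    """State mean log profile excluding cell-cycle and patient effects."""
    lp = beta.copy()
    lp[spec.marker_genes] += spec.marker_log_effect
    if spec.name in ("QSC", "PSP") and config.stem_program.size:
        lp[config.stem_program] += config.stem_log_effect
    # richness gradient, two reinforcing mechanisms: (i) a state keeps its
    # first diversity_rank programs active and silences the rest; (ii) the
    # more differentiated a state, the more of its transcriptome concentrates
    # in its marker program, depressing detection of everything else at a
    # fixed library size
    for prog in config.diversity_programs[spec.diversity_rank:]:
        lp[prog] -= config.diversity_log_effect
    n_prog = len(config.diversity_programs)
    if n_prog:
        frac = 1.0 - spec.diversity_rank / n_prog
        lp[spec.marker_genes] += config.concentration_log_effect * frac
    return lp


def _largest_remainder(props: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to props (largest remainder)."""
    raw = props * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _sample_cells(
    config: GeneratorConfig,
    rng: np.random.Generator,
    log_profiles: np.ndarray,   # cells x genes, log relative expression
    mito_mean: float,
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Draw NB counts for the given log relative profiles.

    Returns the counts and the mask of cells planted at the high
    mitochondrial level (for QC ground truth)."""
    n_cells, n_genes = log_profiles.shape
    rel = np.exp(log_profiles)
    hi = np.zeros(n_cells, dtype=bool)
    # mitochondrial fraction drawn per cell; MT mass replaced accordingly
    if config.mt_genes.size:
        mean = np.clip(mito_mean, 1e-4, 0.9)
        alpha = mean * config.mito_frac_conc
        betap = (1 - mean) * config.mito_frac_conc
        f = rng.beta(alpha, betap, n_cells)
        if config.mito_high_frac > 0:
            hi = rng.random(n_cells) < config.mito_high_frac
            f[hi] = config.mito_high_level
        mt_mask = np.zeros(n_genes, dtype=bool)
        mt_mask[config.mt_genes] = True
        rel_mt = rel[:, mt_mask]
        rel_rest = rel[:, ~mt_mask]
        rel_rest = rel_rest / rel_rest.sum(axis=1, keepdims=True) * (1 - f)[:, None]
        rel_mt = rel_mt / rel_mt.sum(axis=1, keepdims=True) * f[:, None]
        p = np.empty_like(rel)
        p[:, mt_mask] = rel_mt
        p[:, ~mt_mask] = rel_rest
    else:
        p = rel / rel.sum(axis=1, keepdims=True)
        f = np.zeros(n_cells)
    s = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)
    mu = p * s[:, None]
    lam = rng.gamma(config.dispersion, mu / config.dispersion)
    counts = rng.poisson(lam)
    if config.dropout_extra > 0:
        keep = rng.random(counts.shape) >= config.dropout_extra
        counts = counts * keep
    return sparse.csr_matrix(counts, dtype=np.int64), hi


def _phases(rng: np.random.Generator, n: int, cycling: bool, p_cycle: float = 1.0) -> np.ndarray:
    """Cell-cycle phase labels; cycling cells split evenly between S and G2M."""
    ph = np.full(n, "G1", dtype=object)
    if cycling and n:
        cyc = rng.random(n) < p_cycle
        which = rng.random(n) < 0.5
        ph[cyc & which] = "S"
        ph[cyc & ~which] = "G2M"
    return ph


def _apply_cycle(config: GeneratorConfig, lp: np.ndarray, phases: np.ndarray,
                 scale: float = 1.0) -> np.ndarray:
    out = lp.copy()
    s_rows = phases == "S"
    g_rows = phases == "G2M"
    out[np.ix_(s_rows, config.s_genes)] += config.cycle_log_effect * scale
    out[np.ix_(g_rows, config.g2m_genes)] += config.cycle_log_effect * scale
    return out


def _uns_annotations(config: GeneratorConfig) -> dict:
    return {
        "gene_sets": gene_sets(config),
        "surface_genes": surface_genes(config),
        "lr_pairs": [list(p) for p in lr_pairs()],
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: GeneratorConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the two-condition cohort: AML and healthy-control samples.

    Returns an AnnData (cells x genes, raw counts) with obs columns
    ``sample/patient/condition/timepoint`` plus ``true_*`` truth columns, and a
    :class:`GroundTruth` with per-sample planted compositions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    beta = _base_log_means(config, rng)
    profiles = {s.name: _state_log_profile(config, beta, s) for s in config.states}
    specs = {s.name: s for s in config.states}
    leuk = [s.name for s in config.states if s.is_leukemia]

    n_pat = config.n_patients_aml + config.n_patients_hc
    u = rng.normal(0.0, config.patient_effect_sd, (n_pat, config.n_genes))

    samples = ([(f"AML{i + 1:02d}", "AML", i) for i in range(config.n_patients_aml)]
               + [(f"HC{i + 1:02d}", "HC", config.n_patients_aml + i)
                  for i in range(config.n_patients_hc)])

    blocks, obs_rows = [], []
    comp_rows, leukfrac = {}, {}
    state_names = [s.name for s in config.states]
    for sample, cond, pat_i in samples:
        base = np.array([s.prop_aml if cond == "AML" else s.prop_hc for s in config.states])
        props = base
        if config.composition_concentration is not None:
            nz = base > 0
            draw = rng.dirichlet(base[nz] * config.composition_concentration)
            props = np.zeros_like(base)
            props[nz] = draw
        counts_per_state = _largest_remainder(props, config.cells_per_sample)
        lp_rows, states_cells, phase_cells = [], [], []
        for sname, k in zip(state_names, counts_per_state):
            if k == 0:
                continue
            spec = specs[sname]
            lp = np.tile(profiles[sname], (k, 1))
            ph = _phases(rng, k, spec.cycling)
            lp = _apply_cycle(config, lp, ph)
            lp_rows.append(lp)
            states_cells.extend([sname] * k)
            phase_cells.extend(ph.tolist())
        lp_all = np.vstack(lp_rows) + u[pat_i]
        mito_mean = (config.mito_frac_mean_aml if cond == "AML"
                     else config.mito_frac_mean_hc)
        counts, hi = _sample_cells(config, rng, lp_all, mito_mean)
        blocks.append(counts)
        for j, (st, ph) in enumerate(zip(states_cells, phase_cells)):
            obs_rows.append((f"{sample}_c{j:04d}", sample, f"P_{sample}", cond,
                             st, ph, bool(hi[j])))
        if cond == "AML":
            n_leuk = sum(k for sname, k in zip(state_names, counts_per_state) if sname in leuk)
            comp_rows[sample] = {
                sname: (counts_per_state[state_names.index(sname)] / n_leuk if n_leuk else 0.0)
                for sname in leuk
            }
            leukfrac[sample] = n_leuk / config.cells_per_sample

    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "sample", "patient", "condition",
                                          "true_state", "true_phase", "true_mito_high"]
                       ).set_index("cell_id")
    obs["timepoint"] = "T0"
    obs["true_malignant"] = obs["true_state"].isin(leuk)
    var = pd.DataFrame(index=pd.Index(config.gene_names, name="gene"))
    var["mt"] = var.index.str.startswith("MT-")
    adata = ad.AnnData(X=X, obs=obs, var=var, uns=_uns_annotations(config))

    truth = GroundTruth(
        cells=obs[["sample", "patient", "condition", "true_state",
                   "true_malignant", "true_phase"]].copy(),
        sample_composition=pd.DataFrame(comp_rows).T.reindex(columns=leuk).fillna(0.0),
        sample_leukemia_fraction=pd.Series(leukfrac, name="leukemia_fraction"),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# longitudinal pre/post pairs with a planted reprogramming coefficient
# ---------------------------------------------------------------------------

DEFAULT_PRE_COMPOSITION = {"QSC": 0.055, "PSP": 0.300, "GMP": 0.170,
                           "PG": 0.150, "promono": 0.150, "mono": 0.175}
DEFAULT_POST_COMPOSITION = {"QSC": 0.107, "PSP": 0.150, "GMP": 0.170,
                            "PG": 0.150, "promono": 0.150, "mono": 0.273}


def simulate_longitudinal(
    config: GeneratorConfig,
    lam: float,
    cells_per_timepoint: int = 2000,
    pre_composition: dict[str, float] | None = None,
    post_composition: dict[str, float] | None = None,
) -> tuple[ad.AnnData, ad.AnnData, GroundTruth]:
    """Matched pre/post-chemotherapy leukemia samples from one patient.

    Post-treatment the PSP fraction drops and the QSC fraction rises (defaults
    emulate a refractory patient with QSC 5.5% -> 10.7%).  Each post-treatment
    PSP cell's mean profile is the convex mixture ``(1-lam)*PSP + lam*QSC`` of
    the two state profiles, formed on the linear relative-expression scale
    before count sampling; its residual cycling program is attenuated by the
    same factor, so ``lam=0`` reproduces the PSP state exactly and ``lam=1``
    the QSC state exactly.
    """
    if not 0.0 <= lam <= 1.0:
        raise GeneratorError(f"reprogramming coefficient must be in [0, 1], got {lam}")
    config.validate()
    pre_comp = dict(DEFAULT_PRE_COMPOSITION if pre_composition is None else pre_composition)
    post_comp = dict(DEFAULT_POST_COMPOSITION if post_composition is None else post_composition)
    for comp in (pre_comp, post_comp):
        if abs(sum(comp.values()) - 1.0) > 1e-8:
            raise GeneratorError("longitudinal compositions must sum to 1")

    rng = np.random.default_rng(config.seed)
    beta = _base_log_means(config, rng)
    specs = {s.name: s for s in config.states}
    for needed in pre_comp:
        if needed not in specs:
            raise GeneratorError(f"state {needed!r} missing from config")
    profiles = {n: _state_log_profile(config, beta, specs[n]) for n in pre_comp}
    u = rng.normal(0.0, config.patient_effect_sd, config.n_genes)

    mix_psp = np.log((1.0 - lam) * np.exp(profiles["PSP"]) + lam * np.exp(profiles["QSC"]))

    def build(tp: str, comp: dict[str, float]) -> tuple[ad.AnnData, pd.DataFrame, pd.Series]:
        names = list(comp)
        k_per = _largest_remainder(np.array([comp[n] for n in names]), cells_per_timepoint)
        lp_rows, st_cells, ph_cells = [], [], []
        for sname, k in zip(names, k_per):
            if k == 0:
                continue
            spec = specs[sname]
            if tp == "post" and sname == "PSP":
                lp = np.tile(mix_psp, (k, 1))
                ph = _phases(rng, k, True, p_cycle=1.0 - lam)
                lp = _apply_cycle(config, lp, ph, scale=1.0 - lam)
            else:
                lp = np.tile(profiles[sname], (k, 1))
                ph = _phases(rng, k, spec.cycling)
                lp = _apply_cycle(config, lp, ph)
            lp_rows.append(lp)
            st_cells.extend([sname] * k)
            ph_cells.extend(ph.tolist())
        lp_all = np.vstack(lp_rows) + u
        X, _hi = _sample_cells(config, rng, lp_all, config.mito_frac_mean_aml)
        sample = f"LP1_{tp}"
        obs = pd.DataFrame({
            "sample": sample, "patient": "LP1", "condition": "AML", "timepoint": tp,
            "true_state": st_cells, "true_phase": ph_cells,
        }, index=[f"{sample}_c{j:04d}" for j in range(len(st_cells))])
        obs["true_malignant"] = True
        var = pd.DataFrame(index=pd.Index(config.gene_names, name="gene"))
        var["mt"] = var.index.str.startswith("MT-")
        adata = ad.AnnData(X=X, obs=obs, var=var, uns=_uns_annotations(config))
        realized = pd.Series(st_cells).value_counts(normalize=True).reindex(names).fillna(0.0)
        return adata, obs, realized

    pre, pre_obs, pre_real = build("pre", pre_comp)
    post, post_obs, post_real = build("post", post_comp)
    truth = GroundTruth(
        cells=pd.concat([pre_obs, post_obs]),
        sample_composition=pd.DataFrame({"LP1_pre": pre_real, "LP1_post": post_real}).T,
        sample_leukemia_fraction=pd.Series({"LP1_pre": 1.0, "LP1_post": 1.0}),
        extras={"lambda": lam},
    )
    return pre, post, truth


# ---------------------------------------------------------------------------
# bulk mixtures and survival tables
# ---------------------------------------------------------------------------

def true_state_profiles(adata: ad.AnnData, state_col: str = "true_state",
                        states: tuple[str, ...] = LEUKEMIA_STATES) -> pd.DataFrame:
    """Per-state mean raw expression (states x genes) from labeled cells."""
    X = adata.X
    rows = {}
    for st in states:
        mask = (adata.obs[state_col] == st).to_numpy()
        if mask.sum() == 0:
            raise GeneratorError(f"no cells of state {st!r}")
        rows[st] = np.asarray(X[mask].mean(axis=0)).ravel()
    return pd.DataFrame(rows, index=adata.var_names).T


def simulate_bulk_mixtures(
    profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk samples as proportion-weighted sums of state profiles with
    multiplicative log-normal noise.  ``profiles`` is states x genes,
    ``proportions`` samples x states (rows summing to 1)."""
    if (profiles.values < 0).any():
        raise GeneratorError("profiles must be nonnegative")
    if noise_sd < 0:
        raise GeneratorError("noise_sd must be nonnegative")
    P = proportions.reindex(columns=profiles.index)
    if P.isna().any().any():
        raise GeneratorError("proportions columns must match profile states")
    rowsum = P.values.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-8):
        raise GeneratorError("each proportion row must sum to 1")
    rng = np.random.default_rng(seed)
    bulk = P.values @ profiles.values
    if noise_sd > 0:
        bulk = bulk * np.exp(rng.normal(0.0, noise_sd, bulk.shape))
    return pd.DataFrame(bulk, index=proportions.index, columns=profiles.columns)


def simulate_survival(
    compositions: pd.DataFrame,
    betas: dict[str, float] | None = None,
    baseline_rate: float = 0.002,
    censor_rate: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times whose hazard depends on composition.

    ``compositions`` indexes samples and must carry an ``ITH`` column and the
    state-proportion columns referenced by ``betas`` (e.g. ``QSC``).  The
    hazard is ``baseline_rate * exp(sum_b beta_b * x_b)``; censoring is an
    independent exponential with ``censor_rate`` (0 = none).
    """
    if compositions.empty:
        raise GeneratorError("compositions must be nonempty")
    if baseline_rate <= 0 or censor_rate < 0:
        raise GeneratorError("rates must be positive (censor_rate may be 0)")
    betas = dict(betas or {})
    lin = np.zeros(len(compositions))
    for col, b in betas.items():
        if col not in compositions.columns:
            raise GeneratorError(f"betas refer to missing column {col!r}")
        lin = lin + b * compositions[col].to_numpy(dtype=float)
    rate = baseline_rate * np.exp(lin)
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, len(rate))
    else:
        t_cens = np.full(len(rate), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"sample": compositions.index, "time": time, "event": event}
                        ).set_index("sample")
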