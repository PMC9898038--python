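# Methods

`lscape` reimplements, as a tested pipeline, the single-cell analysis used to
dissect relapsed/refractory AML bone marrow: identification of leukemia-like
cells from cluster composition, six-state typing of those cells, Shannon
entropy as an intratumoral-heterogeneity (ITH) index with survival
stratification, signature-matrix bulk deconvolution, longitudinal label
transfer with a reprogramming index, and permutation-tested ligand–receptor
interactions.  Real patient cohorts of this kind are access-restricted, so the
package ships a ground-truthed generator that plants every structure the
statistics are meant to detect; all quantitative claims in the test suite and
the acceptance script are computed against that planted truth.

## Synthetic cohort model

Counts are gamma-Poisson (negative binomial with shared size `dispersion`,
default 2.0).  For cell *c* of state *k* in patient *p*, the mean of gene *g*
is

    mu_gc = s_c * p_gc ,   p_gc ∝ exp(beta_g + delta_gk + u_gp) ,

where `beta_g` is a standard-normal baseline log level, `delta_gk` collects the
state's program effects, `u_gp ~ N(0, patient_effect_sd²)` is a per-patient
log-normal effect (default sd 0.15), and `s_c` is a log-normal library size
(default median 2,500 counts, log-sd 0.25).  The relative profile is
normalized per cell, so *all* depth variation is carried by `s_c`; an extra
Bernoulli dropout (default 5%) is applied to the drawn counts.  Mitochondrial
genes (`MT-` prefix, 10 genes) receive a per-cell expression share drawn from
a Beta distribution (mean 5%, concentration 30) per condition, with an
optional planted high-mito subpopulation for exercising QC.

The default cohort mirrors a two-condition bone-marrow study: 7 AML and 20
healthy-control samples, 500 cells each, 2,000 genes.  Six leukemia-like
states (QSC, PSP, GMP, PG, promono, mono) appear only in AML samples
(70% of an AML sample's cells in expectation); four normal lineages
(HSC-like, erythroid, T, B) appear in both conditions.  Per-sample
compositions are jittered around the baseline with a Dirichlet draw
(concentration 150) and cells are allocated by largest-remainder rounding, so
the recorded truth composition equals the realized label frequencies exactly.

State programs:

- **Markers.** Each state owns a disjoint 40-gene marker block with log effect
  1.2.  Named genes are planted where the downstream analyses look for them:
  CD52, LGALS1, CD47 inside the QSC block; SIGLEC10, SIRPA, CD14 inside the
  mono block; CD99 and ITGA4 in a 30-gene stem program shared by QSC and PSP
  (log effect 1.0).
- **Cell cycle.** Disjoint S and G2M programs (40 genes each, log effect 1.2)
  are expressed by cycling states (PSP, PG); each cycling cell is assigned a
  true phase (S or G2M, equally likely), which is the truth for phase calls.
- **Stemness gradient.** Transcriptional diversity is planted by two
  reinforcing mechanisms tied to a state's `diversity_rank` (QSC/PSP 9,
  HSC-like 8, GMP/PG 6, promono 4, mono 2, other normals 3, out of 10
  30-gene pool programs): a state silences the programs above its rank
  (log effect −1.5), and — because per-cell normalization alone would simply
  re-spread the silenced mass — the more differentiated a state, the more its
  transcriptome concentrates into its own marker block
  (`concentration_log_effect` 2.0 scaled by `1 − rank/10`).  Together these
  make differentiated cells express measurably fewer distinct genes at a
  fixed library size, which is the signal the stemness score estimates.
  Library-size parameters are identical across states, so the gradient is not
  a depth artifact.

Longitudinal pairs are leukemia-only samples from one patient.  Defaults
emulate a refractory patient (QSC 5.5% → 10.7%, PSP 30% → 15%).  The
reprogramming coefficient λ ∈ [0, 1] mixes each post-treatment PSP cell's
relative mean profile as `(1−λ)·PSP + λ·QSC` on the linear scale before count
sampling, and attenuates its residual cycling program by `1−λ`; λ=0 reproduces
PSP exactly and λ=1 QSC exactly.

Bulk mixtures are proportion-weighted sums of state mean-expression profiles
with multiplicative log-normal noise.  Survival times are exponential with
hazard `baseline_rate · exp(beta_ITH·ITH + beta_QSC·p_QSC)` and independent
exponential censoring.

What the generator does **not** emulate: mutational genotypes, doublets,
ambient RNA, batch chemistry, cross-patient marker variability, and continuous
differentiation (states are discrete).  Passing tests therefore demonstrate
that the statistics recover planted structure under a standard noise model,
not that they would achieve the same accuracy on real bone marrow.

## Pipeline stages and numerical choices

**QC and normalization.** Cells are kept with 200–6,000 expressed genes and
mitochondrial fraction ≤ 0.2 (configurable; conventional values — the source
analysis reports only resulting cell counts).  Genes seen in <3 cells are
dropped.  Expression is scaled to 10,000 counts per cell and log1p-ed, zeros
preserved.

**Reduction and clustering.** Highly variable genes (default 1,000) by
within-bin normalized dispersion (20 mean-expression bins); z-scaling clipped
at ±10; top 30 principal directions by randomized SVD with a fixed sign
convention (largest-magnitude loading positive) and seeded random state; kNN
graph (k=15, Euclidean, symmetrized).  The 2D embedding used by the density
map is the first two PCs — deterministic, and nothing downstream depends on
the embedding beyond that visualization.  Clustering is Leiden
(RBConfiguration) at resolution 3.0 by default, deliberately over-clustered so
cluster composition, not cluster identity, carries the malignancy signal.  No
cross-sample integration is performed; `reduce_and_graph` accepts externally
corrected PCs if a dataset needs it.

**Malignancy.** A cluster is leukemia-like iff its AML-cell fraction
f_k ≥ θ (default 0.9); an enrichment variant (f_k over the global AML
fraction ≥ ρ) is available behind a switch.  Healthy-control cells are never
labeled leukemia-like regardless of cluster.  The density map splits the
embedding bounding box into 400×400 half-open bins, normalizes each
condition's bin counts to 1 and reports log2 ratios with pseudocount
ε = 1/max(condition totals).

**Scores and states.**  Module scores use the binned-control construction
(24 mean-expression bins, 100 control genes per set gene, seeded sampling).
The stemness score is a transcriptional-diversity statistic: per-cell
expressed-gene count, per-gene Pearson correlation with that count, mean
expression of the top 200 correlated genes, 3 steps of kNN diffusion
(α = 0.5), then rank-scaling to [0, 1] (ties map to 0.5).  It is validated by
rank correlation with the planted differentiation order, not by equality with
any external tool.  The proliferation and lineage module scores that feed
state assignment receive the same kNN diffusion — neighbors are almost always
same-state, so diffusion shrinks per-cell sampling noise around the decision
thresholds without moving state means; the S/G2M scores behind each cell's
phase call stay raw so phase remains a per-cell property.  Assignment is
rule-based: argmax lineage program (ties broken stem > GMP > granulocyte >
promono > mono), stem cells split at proliferation τ = 0 into QSC (≤ τ) vs
PSP, granulocyte-lineage cells in S/G2M are PG, else GMP.  τ = 0 is this
package's convention; the source analysis placed the boundary along a
pseudotime trajectory it does not parameterize.  Surface markers are
one-vs-rest Wilcoxon rank-sum tests (normal approximation, continuity and tie
corrected) restricted to a surface-gene list, BH-FDR ≤ 0.05 and logFC ≥ 0.25.

**ssGSEA.** Genes are ranked per cell; the score is the summed difference of
the rank-weighted (weight = rank^0.75) in-set running fraction and the uniform
out-set ECDF.  The in-set running weight is normalized by its exchangeability
expectation rather than the realized set weight, which makes a random set
score exactly zero-mean, and the sum is scaled by its range (set wholly at the
top vs wholly at the bottom), so scores are comparable across set sizes.

**ITH and survival.** Per-sample compositions over the six states among
leukemia-like cells; ITH is base-2 Shannon entropy (0·log 0 := 0), unnormalized
by default with an H/log2(6) variant behind a flag (the source's base and
normalization are unstated).  Median splits send ties to Low and refuse
degenerate splits; a two-variable median cross-split provides the
QSC-high/PSP-low style grouping.  Kaplan–Meier estimation and the log-rank
test are delegated to lifelines behind the module's interface; the tests check
them against hand-computed product-limit values and Monte-Carlo calibration
under the generator.

**Deconvolution.** Signatures take each state's top 50 positive one-vs-rest
markers (BH-FDR ≤ 0.05, ranked by logFC) and store linear-scale state means
over the marker union.  Bulk profiles are restricted to shared genes and
rescaled to the signature's mean column total — one common scalar, preserving
mixture linearity — then solved by NNLS and renormalized to proportions.
Because every nonnegative coefficient vector is a simplex direction times a
scale, the renormalized NNLS solution equals the simplex-constrained best
mixing direction; the tests verify this against an exhaustive grid-search
oracle.  ν-SVR, quantile normalization and batch ("S-mode") corrections of
CIBERSORT-family tools are deliberately not reproduced; accuracy is validated
against planted mixtures instead.

**Longitudinal.** Label transfer projects query cells through the reference
HVG/scaling/loadings and takes a k=15 nearest-neighbor majority vote (ties:
smaller mean neighbor distance, then fixed state order) — chosen over
anchor-based integration for determinism.  The reprogramming index z-scales
the chosen differential genes with pooled *pre-treatment* statistics (so a
global post-treatment shift cannot move it), computes pre-QSC, pre-PSP and
post-PSP centroids, and reports R = d(X,P) / (d(X,P) + d(X,Q)).  For λ sweeps
the gene list is the pre-treatment QSC-vs-PSP differential set: the axis
between the two pre-treatment centroids must be defined even when
post-vs-pre differential expression within PSP is empty (λ = 0).

**Interactions.** CellPhoneDB-style mean-of-means score per (ligand,
receptor, sender, receiver), evaluated only when ≥10% of cells express the
gene on both sides; the null permutes state labels across all cells (the
single-patient setting), p = (1 + #{null ≥ obs}) / (n_perm + 1) with n_perm
default 1,000 and a hard floor of 100.

**Orchestration.** One global seed fans out per stage as
`crc32(stage_name) XOR seed mod 2^31`, so toggling optional stages never
changes earlier results.  Reports carry no timestamps and all floats are
rounded to 10 decimals before serialization, making reruns bit-identical.

## Problem sizes used by tests and the acceptance script

The acceptance checks run the default cohort (27 samples × 500 cells × 2,000
genes, ~13.5k cells).  Monte-Carlo calibrations use 500 null gene pairs with
199 permutations (the p ≤ 0.05 rejection probability is then exactly 0.05
under the null), 500 null and 200 alternative survival replicates at 100–200
subjects, 20 generator seeds for the reprogramming-index bounds at 2,000
cells per timepoint (the scale at which centroid noise is small relative to
the QSC–PSP axis), and a 20% holdout for label transfer.  Unit tests use a
1,000-gene, 120-cell-per-sample cohort.

## Known limitations

- Discrete states with disjoint markers make clustering and transfer easier
  than in real AML, where programs overlap and vary across patients; accuracy
  numbers on synthetic data are upper bounds.
- The malignancy rule depends on healthy cells being present in every normal
  region of expression space; a lineage absent from controls would be called
  leukemia-like.
- The stemness score assumes richness increases toward stem states; real
  datasets with strong depth gradients need the library-size independence the
  generator guarantees by construction.
- The ITH index ignores within-state heterogeneity; two samples with the same
  six-state mixture score identically.
- `paired_shift_test` returns p = 1 with a no-information flag when all paired
  differences are zero rather than erroring, so pipelines can continue.
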