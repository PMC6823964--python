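# Methods

This note documents the models, algorithms, and simulation choices behind
`wheatgs`, in the order data flows through the pipeline.

## Genotype model and coding

Lines are fully homozygous inbreds. Biallelic markers are coded −1 / +1 for
the two homozygous classes, 0 for residual heterozygotes, `NaN` for missing
calls. Allele frequencies use per-haplotype doses `(code + 1) / 2`, so each
line carries 0 or 2 copies of the `+1` allele.

## Synthetic populations

Two panel generators are provided.

**Balding–Nichols panel** (`simulate_panel`). Ancestral allele frequencies
are uniform on a configurable MAF window; each subpopulation draws its own
frequency from `Beta(p(1−F)/F, (1−p)(1−F)/F)` with divergence `F`; lines are
independent Bernoulli draws within their subpopulation. Markers sit on a
genetic map (default 21 chromosomes × 1.5 Morgans; marker density and map
length are configuration, not inference). Monomorphic markers are redrawn so
every marker segregates. Because loci are drawn independently, the only LD
in this panel is global population structure. That is exactly right for
testing structure correction in association scans, but it means marker
effects fitted on such a panel generalize *only* through subpopulation
alignment — whole-panel prediction accuracy then depends on the accident of
whether the simulated trait projects onto the structure axes.

**Family panel** (`simulate_family_panel`). Breeding-program germplasm
descends from a limited founder pool, which creates within-chromosome LD.
This generator draws a small founder set per subpopulation under the
Balding–Nichols model, then builds each panel line as a recombinant inbred
mosaic of a random founder pair from its subpopulation. Close markers reach
r² ≈ 0.15 against an unlinked baseline of ≈ 0.06, and cross-validated
prediction accuracy becomes stable across seeds (≈ 0.45–0.60 at the default
scale) instead of structure-dependent. The end-to-end demonstrations and the
reproduction script use this panel; the Balding–Nichols panel remains the
reference for the structure-specific tests.

**Biparental progeny** (`simulate_biparental`). Crossovers follow the
Haldane no-interference model: per chromosome a Poisson number of crossovers
with mean equal to map length in Morgans, positions uniform, starting phase
random. Doubled haploids are one meiosis with the gamete doubled; RILs are
approximated as DHs on a map expanded by factor 2, which reproduces the
extra effective recombination accumulated over selfing without simulating
the generations (adequate for homozygous-line LD structure). For two
markers `d` Morgans apart the DH recombination fraction is
`(1 − e^(−2d))/2`.

**Traits** (`TraitArchitecture`, `simulate_phenotypes`). Genetic values are
strictly additive: `g_i = μ + Σ_j x_ij β_j` over QTL plus optional
major-gene loci. Major genes stay ordinary markers in the genotype matrix so
they can be excluded or promoted to fixed covariates downstream, mirroring
how photoperiod/vernalization assays share the genotyping platform. Plot
values add an environment main effect, a genotype-by-environment draw, a
block-within-environment effect, and residual noise, all Gaussian. When a
target entry-mean heritability is given, the residual SD is derived from

    H² = σ²_G / (σ²_G + σ²_GxE/e + σ²_E/(e·r))

with `e` environments and `r` replicates; if the configured G×E variance
alone exceeds the implied non-genetic budget (narrow crosses have small
σ²_G), G×E is shrunk to half the budget and the residual takes the rest.
All generators are bit-reproducible given their spec and seed.

## Genotype processing

QC removes markers below a MAF floor (default 0.05) or above a missingness
ceiling (default 0.2); thresholds are configuration because no universal
values exist. Missing-data imputation is an EM-style scheme on a shared
marker covariance: each iteration replaces every line's missing scores with
their conditional expectation given that line's observed scores under a
multivariate-normal model, then re-estimates means and covariance from the
completed matrix. The covariance carries a ridge (1e−6) on its diagonal so
conditioning stays well-posed when markers far outnumber lines, and the
low-rank structure is exploited through the Woodbury identity so no
markers-by-markers matrix is ever formed. Convergence is declared when the
largest imputed-value change drops below 1e−4 (50 iterations maximum, with
a warning); imputed values are clipped to [−1, 1]; observed entries are
never modified.

The additive genomic relationship matrix is the VanRaden construction
`K = WW′/c`, `W` the column-centred score matrix,
`c = 2 Σ_j p_j (1 − p_j)` with sample allele frequencies. Principal
components come from the SVD of `W`, with each component's sign fixed by
making its largest-magnitude loading positive so runs are comparable across
platforms.

## Phenotype model

The plot model is `Y = μ + Env + Entry + Entry×Env + Block(Env) + ε` with
environments fixed and the rest random. For the balanced trials the
generator produces, the restricted likelihood factorizes over orthogonal
ANOVA strata (entries; entry×env; blocks-in-env; residual), each
contributing `−½(df·log λ_s + SS_s/λ_s)` with `λ_s` a known linear
combination of the four variance components. REML is a bounded L-BFGS-B
maximization over the non-negative components starting from the ANOVA
estimators; interior solutions coincide with classical ANOVA-REML, negative
ANOVA solutions are handled by the bound (reported as 0 with a flag).
Unbalanced tables are rejected rather than silently mis-fitted. Entry BLUPs
shrink entry means toward the grand mean by
`σ²_G / (σ²_G + σ²_GxE/e + σ²_E/(e·r))`. With one environment the G×E
component is not estimable and is fixed at 0 (warning); likewise the
residual with one replicate. Heritability uses the entry-mean formula above
and is conventionally reported to two decimals.

## Prediction engine

`solve_mixed` fits `y = Xβ + Zu + ε`, `u ~ N(0, Kσ²_u)` by the spectral
method: eigendecompose `ZKZ′` projected off the fixed effects once, then
maximize the restricted likelihood over `log λ` (`λ = σ²_e/σ²_u`) by bounded
Brent search on [−10, 10] with tolerance 1e−8. Solutions at a search bound
are flagged `boundary` instead of silently clamped — with weakly structured
`ZZ′` (many independent markers, few lines) the ratio is genuinely poorly
identified and the flag is meaningful. Ridge (marker-effect) and GBLUP
(kinship) parameterizations are the same model: with `K = WW′/c` the fitted
ratios map as `λ_GBLUP = λ_ridge/c` and `Z·û_ridge` equals the GBLUP line
effects; the test suite verifies this equivalence against the spectral path
and verifies fixed-ratio solutions against a dense Henderson
mixed-model-equation solve.

GEBVs for new lines are `G_new·û` on the training marker set (apply
`common_markers` first); the fixed part (intercept + major-gene covariates)
can be added so known-gene signal counts toward prediction. Accuracy is the
plain Pearson correlation between GEBVs and observed entry BLUPs on the
overlap — no √H² deflation, negative values reported as-is, zero variance an
error rather than a silent 0.

## Association scan

The scan exists to pick marker subsets on training lines only, so marker
choice never sees validation lines. A null model (intercept + 3 genotype
PCs fixed, polygenic term with kinship `K`) is fitted once by REML; every
marker is then tested by GLS with the null variance structure held fixed —
the standard two-stage approximation to per-marker REML. On whitened,
projected data the per-marker test is an exact 1-df regression F-test,
which (a) collapses onto simple linear regression when `K = I` and no PCs
are requested, and (b) keeps the null type-I error at its nominal level in
small samples. Markers below the MAF floor are flagged untested, never
given p = 1. Subsets use raw p-value thresholds (0.15/0.10/0.05 by
convention) without multiplicity correction — the subsets are feature
selection, not discovery claims — and an empty subset is an explicit signal
so callers fall back to the whole genome.

## Evaluation designs

All schemes persist per-replicate accuracies (mean and SE are derived, SE =
sd/√n) and are bit-reproducible given design and seed. Defaults mirror the
study design this package replays: GWAS→GS with 10 cycles of TP 219 / VP
20; TP-size sweep over 25–150 by 25 at VP 60; subpopulation cross-prediction
at TP 50 / VP 30; fixed-effect comparison under 10-fold CV with the panel
subsampled so every fold trains on exactly `tp_size` lines; independent
prediction on the marker intersection with simple-matching coefficients
reported alongside.

## Selection response

`R = H²·S`, `S = μ_sel − μ_pop`, at 10% intensity. Phenotypic selection
takes the top k lines on phenotype; genomic selection the top k on mean
held-out GEBV over repeated k-fold CV (10 rounds by default); random
selection averages 10 seeded draws; marker-based selection takes every
carrier of the favorable allele at all listed loci (dropping loci from the
least significant end if no line carries all — with four or more loci the
carrier set collapses, which is why carrier-set semantics rather than top-k
is used). The combined strategy selects the lines present in both top-k
sets: a subset of the phenotypic top-k enriched for lines both rankings
agree on, which is how combining criteria can out-select phenotype alone; a
rank-sum fill is used only if the agreement set is empty. Percent change
versus phenotypic selection is computed from responses rounded to two
decimals, the precision at which selection responses are conventionally
reported. A `measure` argument separates the evaluation scale from the
selection criterion (select on averaged per-dataset BLUPs, measure response
on the across-trials mean), reflecting how multi-environment programs
actually operate; ties at the k-th rank break by line ID for
reproducibility.

## What the simulations do and do not show

The generators reproduce the statistical skeleton the methods rely on:
subpopulation structure, founder-derived linkage LD, additive polygenic
traits with calibrated entry-mean heritability, balanced multi-environment
noise, and homozygous biparental segregation. They omit dominance and
epistasis, selection during line development, genotyping error,
ascertainment bias of array markers, spatial field trends, and unbalanced
augmented designs. Passing tests therefore demonstrate the estimators and
designs behave correctly under the assumed model, not that real wheat data
meet those assumptions. Directional claims (accuracy rising with training
size, related populations predicting better, GWAS subsets helping
oligogenic but not polygenic traits, major-gene covariates helping) are
each scored over ten independently seeded meta-replicates at reduced scale
(panels of 200–240 lines, 600–1000 markers) with an 8-of-10 pass rule;
the strategy-ordering check uses 20 panels of 240 lines at H² = 0.48 on the
yield scale (mean 3.17, entry-mean SD ≈ 0.37 t/ha) with a 15-of-20 rule.

## Numerical choices

- REML ratio search: bounded Brent in `log λ ∈ [−10, 10]`, xatol 1e−8;
  variance-component optimizer: L-BFGS-B with non-negativity bounds.
- EM imputation: ridge 1e−6, tolerance 1e−4, max 50 iterations.
- PCA sign fix: largest-|loading| positive.
- PSD tolerance for relationship matrices: min eigenvalue
  > −1e−8 · trace/n.
- Ties in selection rankings break by line ID (stable, logged in metadata).
- Degenerate inputs raise: all-missing markers, empty marker intersections,
  zero-variance accuracy inputs, rank-deficient fixed designs (naming the
  collinear columns), non-PSD kinships.
- The pipeline derives one sub-seed per stage from the master seed via
  `SeedSequence([master, sha256(stage)[:8]])`, so stages re-run in
  isolation reproduce their outputs exactly.
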