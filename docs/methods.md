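# Methods

## The model

`grpisis` targets gene-based selection of rare genetic variants for a
quantitative trait. SNP dosages (0/1/2 copies of the minor allele) are
naturally partitioned into genes, giving the grouped linear model

    y = X_1 β_1 + … + X_J β_J + Z γ + ε,      ε ~ N(0, σ² I),

where `X_j` (n × p_j) holds the dosages of gene j's SNPs, `Z` holds the
forced-in covariates sex, age and smoking, and the architecture is
**bilevel sparse**: only a few genes have nonzero blocks `β_j`, and each
nonzero block is itself sparse. With tens of thousands of SNPs — many of
them singletons, observed in a single carrier — and only hundreds of
samples, no SNP-level model is identifiable; gene-level selection restores
identifiability and pools the weak signals of rare variants within a gene.

## Screening score

Every screening decision uses the residual mean square of an OLS fit,

    RSS/df,   df = n − (#estimated coefficients, intercept included),

smaller is better. The intercept is always estimated and never counted
against the SNP caps (the caps of `C` and `C·k` below count SNPs only; the
three covariates ride along in every fit). Rank-deficient subsets —
routine with singleton-heavy genotype blocks — are fit by the minimum-norm
least-squares solution and flagged with a warning. Forward stepwise
selection adds the candidate column with the largest RSS reduction and
stops early when the best relative reduction falls below 1e-10, which
keeps numerically collinear columns out of the model.

The df convention is a package decision: it makes RSS/df the usual
residual mean square, so a gene that needs more SNPs to achieve the same
fit is penalized in the ranking.

## Group SIS and the two iterative procedures

**Group SIS** fits each gene marginally (its SNPs + covariates + intercept)
and ranks genes by ascending RSS/df. Genes with more than `C = 5` SNPs
contribute their best `C` SNPs by forward stepwise selection, so no
marginal model exceeds `C + 3` predictors. Ties break toward the gene
listed earlier; degenerate fits rank last.

**Procedure 1** (default `K = 12` iterations) is grouped forward selection:
iteration 1 takes the best marginal gene; iteration k re-runs stepwise
selection over the SNP union of the selected genes plus each candidate
gene, with the whole model capped at `C·k` SNPs + 3 covariates, and adds
the candidate with the smallest RSS/df. Previously selected genes' SNP
supports are deliberately *not* frozen between iterations — the cap
applies to the whole model, so earlier genes can trade SNPs for better
ones as the model grows. Exactly `min(K, J)` genes come out.

**Procedure 2** (default cap 10 iterations) adds `k0 = 5` genes per
iteration and allows deletion. Candidate genes are ranked conditionally on
the retained model: the retained SNPs (those with nonzero coefficients in
the last deletion step) and covariates are forced in, and each candidate
gene contributes up to `C` of its own SNPs. After adding the `k0` best,
a group-penalized path (group LASSO or group MCP) is fit on *all* SNPs of
the retained + new genes — the per-gene cap applies only to screening
fits, since the deletion step selects whole genes — with covariates
unpenalized; λ is chosen by AIC or BIC and every gene whose block is
entirely zero is deleted (previously retained genes included). The loop is
**stable**, and stops, when all `k0` newly added genes are deleted in the
same iteration: deleting some new genes while keeping others still makes
progress, deleting all of them means none is possible. Covariates are
never penalized and never deletable.

## Group penalties

On centered data the deletion step minimizes

    (1/2n) ‖y − Xβ − Zγ‖² + Σ_j ρ(‖β_j‖₂ ; λ w_j, γ_MCP)

with group weights `w_j = √p_j` rescaling λ per group. `ρ(t; L) = L·t`
gives the group LASSO; the minimax concave penalty

    ρ(t; L, γ) = L·t − t²/(2γ)  for t ≤ γL,   γL²/2 otherwise,

with default concavity γ = 3, gives group MCP — unbiased for large blocks
and therefore more aggressive at discarding marginal ones. Applying the
weight by rescaling λ (rather than multiplying the whole penalty) keeps
the firm-threshold update well defined for every group size at the default
γ.

Each block is groupwise orthonormalized before fitting (`Q_jᵀQ_j = n I`,
via SVD with rank truncation at 1e-10 relative), which makes the block
update an exact (soft or firm) threshold; coefficients are mapped back to
the dosage scale afterwards, with minimum-norm back-maps for
rank-deficient blocks (duplicate columns share the coefficient). The
penalty is assessed on the orthonormalized block norms — the conventional
setup for grouped penalties. Cyclic block coordinate descent with
active-set acceleration runs until the largest coefficient change drops
below 1e-7, capped at 10,000 cycles (a cap hit marks the point
non-converged and aborts procedure 2 with its iteration trace). Blocks
whose norm lands within 1e-8 of zero (relative to the response scale) are
snapped to exactly zero: boundary thresholding can leave eps-level blocks
that would otherwise corrupt the active set and the model df.

The λ path starts at `λ_max = max_j ‖Q_jᵀ r₀‖₂ / (n w_j)` (r₀ the
covariate-adjusted response), where every block is exactly zero, and takes
100 log-spaced points down to 0.001·λ_max, warm-starting each fit from the
previous one. MCP's multiple local minima are handled by this warm-started
continuation only — no restarts, for determinism. Model selection uses

    AIC = n·log(RSS/n) + 2·df,   BIC = n·log(RSS/n) + log(n)·df,

with df = the count of nonzero coefficients including intercept and
covariates; ties go to the larger λ (sparser model), and a zero-RSS point
is flagged saturated.

## The synthetic cohort generator

The simulator emulates the structure of a GAW17-style mini-exome panel at
reduced scale; its defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| samples n | 700 | mini-exome cohort scale |
| genes J | 500 | ~3,800 SNPs at mean gene size 7.6 |
| gene sizes | geometric, mean 7.6, clipped to [1, 40] | heavy-tailed, echoes 24,487 SNPs / 3,205 genes |
| singleton share | 0.385 | echoes 9,433 / 24,487 singleton SNPs |
| other MAFs | log-uniform on [1/(2n), 0.45] | rare-variant-dominated spectrum |
| causal genes | 10 | sparse at the gene level |
| causal SNPs/gene | 1–4 | sparse within genes |
| effect sizes | U(0.4, 1.0) per dosage, positive | detectable but not dominant rare-variant effects |
| covariate effects | sex 0.5, age 0.01/yr, smoking 0.4 | modest, always-present confounding |
| noise sd / replicate | 1.0 | unit-scale residual noise |
| replicates R | 200 | noise-level presets below |

Genotypes are Binomial(2, q) per sample (Hardy–Weinberg), singletons get
exactly one heterozygous carrier, and monomorphic draws are converted to
singletons so every SNP is polymorphic. Causal genes are sampled among
genes with at least one SNP of MAF ≥ 0.01, and causal SNPs prefer that
range — a purely singleton-borne signal is undetectable by any method at
this n, and real panels' implicated variants have multiple carriers.
Causal SNPs are flagged nonsynonymous in the group map (background SNPs
are flagged at rate 0.55), so annotation pre-filtering never removes true
signal. Replicates share the genetic + covariate signal and differ only in
noise; averaging all R replicates gives the low noise level, consecutive
blocks of 10 give medium, single replicates give high (residual sd scales
as 1/√R).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (an optional injector copies columns across genes to
reproduce the duplicate-SNP aliasing hazard, but there is no graded LD),
population stratification or relatedness, non-Gaussian noise, and any
specific real trait's generating model. Passing tests therefore show that
the procedures recover bilevel-sparse architectures under independent
Hardy–Weinberg genotypes — not that they are robust to confounding or LD.

## Evaluation

A selection is scored against truth at the gene level: NTP (selected and
causal), NFP (selected, not causal), FDP = 100·NFP/(NTP+NFP) percent,
with the FDP of an empty selection defined as 0 (no discoveries, no false
discoveries). Across datasets the summary reports the mean and sd of the
per-dataset values — in particular the mean of per-dataset FDPs, not the
FDP of pooled counts. SNP-level hits inside selected genes are reported in
the selection reports without a percent summary.

## Problem sizes and numerical choices

The bundled benchmark (`grpisis.experiments.support_recovery_experiment`,
also run by `scripts/acceptance.py`) uses 10 cohorts of n = 700, J = 500,
10 causal genes, R = 50 replicates averaged — a scale where a full
group-LASSO path over all ~3,800 SNPs and the complete procedure-2 loop
run in well under a minute per cohort. The pure-noise stability checks use
n = 300 with 40 three-SNP genes, a regime where BIC's consistency (penalty
log(n)·p_j against a best-of-J chance RSS reduction) has comfortable
margin. All randomness flows from a single integer seed through
`numpy.random.default_rng`; ties everywhere break toward the
earlier-listed gene or lower column index, so reruns are bit-identical.

## Known limitations

- Group MCP here penalizes the block norm, so it selects whole genes;
  within-gene SNP sparsity arises only through rank truncation of
  degenerate blocks, not through a composite (bilevel) penalty.
- Conditional ranking in procedure 2 forces in the retained SNPs rather
  than re-running the full stepwise union of procedure 1 — the cheaper of
  the two consistent readings of "similar to procedure 1", chosen so the
  candidate sweep stays O(n·p) per iteration.
- Cross-gene duplicate columns make gene attribution non-identifiable;
  `find_duplicate_snps` diagnoses the hazard but nothing can resolve it
  from genotype data alone.
- Missing genotypes are column-mean imputed for fitting; MAF computations
  exclude imputed (fractional) entries from allele counts.
- Binary/disease phenotypes, overlapping groups, SCAD, and
  cross-validated λ selection are out of scope.
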