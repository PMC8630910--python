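# Methods

## The data model

Single-cell qPCR reports a threshold cycle CT per (cell, gene) reaction.
The pipeline works on expression `E = total_cycles - CT` for detected
reactions (`CT < LOD`) and `E = 0` otherwise.  Defaults: LOD 28 cycles
(at or beyond it a reaction is scored non-detected), 40 PCR cycles (the
cycle count is an instrument convention and is configurable).  Detected
expression therefore lives in `(total_cycles - LOD, total_cycles]` — a
censored window — and zeros are a mixture of true silence and dropout.

Cell QC: doublet/empty capture flags are removed first; the failure
score (per-cell CT sum, missing reactions contributing `total_cycles` so
low-yield cells are penalized) flags cells above `mean + 2·sd`.  The
mean/sd are computed per capture run (donor x cell type) by default
because CT totals carry batch effects; a global option exists.  Whether
the original procedure pooled runs is not documented; the choice is
exposed as a parameter.

## The association ensemble

Genotype enters as minor-allele dosage (0/1/2), additive in the three
regressions and categorical in the ANOVA.  All four methods treat the
donor as the statistical unit for the genotype contrast, which is the
point: cells within a donor share both a genotype and an expression
level, and treating them as independent replicates (the naive per-cell
Mann-Whitney scan, kept for comparison) inflates type I error several
fold under realistic person-level heterogeneity.

*Tweedie (PQL).*  Quasi-model `log mu = b0 + b1 g + u_i`, variance
`phi mu^p`, `1 < p < 2` (compound Poisson-gamma shape: point mass at
zero, continuous positive part).  Fitted by penalized quasi-likelihood:
iterated weighted random-intercept LMM on the working response, weights
`mu^(2-p)`.  Quasi-likelihood only requires the mean model, which is the
reason this route is robust to the censored window.  The power index is
profiled over {1.1, 1.3, 1.5, 1.7, 1.9} by extended quasi-likelihood
(zeros enter the EQL density term through a floored surrogate, the
standard Nelder-Pregibon device); a fixed power can be supplied and is
used where the power is nuisance (calibration studies) to save time.

*Logistic (adaptive Gauss-Hermite ML).*  Random-intercept logistic
model on the detection indicator.  The marginal likelihood integrates
the donor intercept by Gauss-Hermite quadrature centered and scaled at
each donor's conditional mode (21 nodes).  Plain, uncentered quadrature
is *not* sufficient here: with intercept sd above ~1 and tens of cells
per donor it mislocates the optimum badly (estimates diverging from the
reference implementation and null rejection near 0.10).  L-BFGS-B with a
Nelder-Mead polish on line-search stalls; standard errors from a
central-difference Hessian.  Genes with average on-proportion > 0.98
carry no binary information and are excluded from this method only;
boundary 0.98 is kept (strict `>`).

*Gaussian on nonzero values (REML).*  Random-intercept LMM on the
detected cells only.  The engine is closed-form per group
(Sherman-Morrison), profiles the variance ratio in one dimension, and
reports Satterthwaite degrees of freedom from the curvature of the
restricted likelihood.  In the boundary case (zero estimated intercept
variance) estimate, standard error and df reduce to OLS exactly.

*Proportion ANOVA.*  One-way ANOVA of per-donor on-proportions on
genotype category.  A homozygous-minor group with fewer than 2 donors is
merged with heterozygotes (recorded); zero within-group variance with a
non-zero between-group difference is flagged rather than assigned a
p-value.  Its direction of association is the carrier-vs-major-homozygote
mean proportion difference, so every retained record carries a sign.

*Inference reference.*  Dosage is a between-donor covariate; with ~15
donors, normal-reference Wald tests are anti-conservative.  The Gaussian
model uses Satterthwaite df; the two GLMMs use between-within df
(`n_donors - 2`).  This keeps null calibration near nominal at the cost
of power — with 15 donors, between-person contrasts cap attainable
power, and detection of moderate planted effects at FDR 0.1 lands well
below certainty (the acceptance script measures it directly).  A z
reference would roughly double the null rejection rate; calibration was
judged the binding requirement.

*Multiplicity.*  Benjamini-Hochberg step-up with enforced monotonicity,
applied within each (cell type, method) family across all SNP-gene
pairs; retention is strict `q < 0.1`.  Non-converged or skipped fits
never enter the ranks (their counts are reported); silent NA propagation
would corrupt the step-up.

*Sharing.*  A pair is shared when significant in both subsets with the
same direction, the sign taken from the best-FDR method per cell type
(hits found by different methods need one canonical sign source).
Discordant-direction pairs are counted exclusive in each subset and
flagged.  The sharing-vs-50% and cell-type-imbalance tests are two-sided
exact binomial tests; this is a defined contract of this package, not a
reconstruction of any previously reported test statistic.

## Co-expression

Per-donor Pearson correlation matrices (zeros included — excluding them
is available but not default, since the on/off state is part of the
co-regulation signal), averaged element-wise, eigendecomposed.
Variance explained is eigenvalue / gene count; loadings are
eigenvector x sqrt(eigenvalue), i.e. gene-PC correlations — raw
unit-norm eigenvector entries could never exceed 0.7 for tens of genes
simultaneously, so the 0.7 module threshold only makes sense on scaled
loadings.  Eigenvector signs are fixed (largest-magnitude loading
positive).  "Highly explanatory" components default to PC1 (the leading
share is typically an order of magnitude above the rest); a
dominant-share rule is available.  Cell projection standardizes genes by
the *pooled* mean/sd: per-donor centering would remove donor effects by
construction and make the averaged-vs-pooled comparison meaningless.

## The generator

`simulate_expression` draws, per (cell, gene): a latent log-mean =
gene baseline + shared donor factor (sd 0.5) + gene-specific donor
intercept (sd 1.0) + planted mean effects; detection probability =
logistic(-1.6 + 1.0 x latent + planted detection effects), so dropout is
missing-not-at-random as in qPCR (an MCAR toggle exists for oracle
checks); detected cells get a truncated-normal expression inside the
detection window (sd 2.0 cycles) and `CT = total_cycles - E`;
non-detected cells get CT at or above the LOD, so the transformed zero
pattern is exact by construction.  Genotypes are drawn at HWE.  On/off
genes flip a per-(gene, donor) Bernoulli switch that silences every cell
of that donor.  Co-expression blocks add a per-cell factor on the
expression scale (amplitude in cycles; 4.0 at within-cell sd 2.0 targets
within-block r = 0.8 — window censoring attenuates the realized average
to ~0.6-0.7, which module recovery tolerates comfortably).

The shared donor factor exists because donor heterogeneity that is
*common across genes* is what makes pooled-cell PCA cluster by donor;
without it the averaged-correlation device would have nothing to remove.

What the generator does not emulate: amplification efficiency
differences between assays, melt-curve artifacts, plate/run batch
structure beyond the donor, cell-cycle or cell-size covariates, and any
real linkage structure among the SNPs.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every artifact of real Fluidigm data.

## Problem sizes and numerics

Simulation studies in the tests and acceptance script use the study's
per-donor design (15 donors, ~30-40 cells per subset) with reduced gene
and SNP panels (1 gene for single-fit calibration/recovery, 10-12 genes
x 2-3 SNPs for scan-level studies, 30 genes for co-expression), sizes
chosen so repeated replicates remain cheap while the between-donor
structure — which drives every conclusion — matches the study scale.
Replicate counts: 200 for calibration and recovery, 50 for scan power
and co-expression rates, 20 for null-scan FDR behavior.

Numerical choices: REML profile on log variance ratio over a 19-point
grid plus bounded refinement, boundary checked explicitly; PQL
convergence at 1e-7 on coefficients, 60 iterations max; logistic inner
Newton to 1e-9; finite-difference Hessians with relative steps 1e-3
(GLMM) and 1e-4 (Satterthwaite); eigenvalues clipped at 0 for loadings;
ties in BH broken stably.  Degenerate inputs (all-zero genes,
single-class outcomes, monomorphic SNPs, all-identical values) are
recorded skips, not errors, inside a scan.

## Limitations

- Fifteen donors bound the power of any between-donor test; effects
  below ~1 log-odds or ~1 log-mean unit per allele are unlikely to
  survive FDR on a multi-gene panel.  This is a property of the design,
  not of the estimators.
- PQL is approximate; its p-values rest on the working-model Wald
  statistic and the between-within df convention rather than a true
  marginal likelihood.
- The Tweedie power profile uses extended quasi-likelihood, which is a
  model-selection heuristic; inference conditions on the selected power.
- Sharing classification inherits the per-cell-type significance calls;
  a pair just missing the cutoff in one subset is counted exclusive, so
  shared counts are conservative.
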