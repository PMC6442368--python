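# Methods

## Scope and data model

The package analyses a protein × sample quantitation matrix from DIA mass
spectrometry (linear-scale intensities as emitted by the upstream
extraction software), accompanied by per-protein peptide-support counts,
per-sample metadata (group, processing-date batch, subject, timepoint),
and optional protein annotations (gene symbol, molecular weight from
FASTA), gene sets (GMT) and RNA counts with exon-union lengths. Matrices
carry a `scale` flag (linear / log2) and a provenance tag
(`raw-linear` / `log2` / `combat-adjusted`). The provenance tag is
enforced at stage boundaries: differential expression refuses a
ComBat-adjusted matrix, because batch is handled there by blocking and
adjusting first would distort the error model, while PCA and heatmaps
consume the adjusted matrix. Missing cells are NaN throughout; no stage
imputes.

Contaminant rows (MaxQuant-style `CON__` accessions by default, pattern
configurable) are dropped at read time. Identifier policy: the accession
is the primary key; gene symbols are annotation, and protein/RNA tables
are matched on gene symbol.

## Proteomic ruler

Histones are stoichiometric with DNA, and a diploid human cell carries
`dna_mass_per_cell` = 6.5e-12 g of DNA (configurable). Per sample,

    mass_p   = dna_mass_per_cell * I_p / sum(I_h, h in histones)
    copies_p = mass_p * N_A / MW_p

with N_A = 6.02214076e23 /mol and MW the average (not monoisotopic)
molar mass, since the ruler weighs intact protein. Histone membership is
a gene-symbol list shipped as a text file (H1/H2A/H2B/H3/H4 families,
current and legacy HGNC names) and overridable. Normalization is
per-sample (each sample's own histone sum), making copy numbers invariant
to global intensity rescaling of a sample. Proteins without a molecular
weight are omitted with a warning; a sample with zero histone signal is a
hard error. Coefficients of variation use the unbiased (n−1) standard
deviation because replicate counts are small. Panel ordering ("top k by
abundance") uses the mean over healthy samples of log10 copies.

## Differential expression

Per protein, ordinary least squares of log2 intensity on an intercept,
a case-group indicator, and treatment-coded batch dummies (largest batch
as reference — arbitrary but reproducible). Only proteins with ≥ 2
supporting peptides are tested; within the contrast, each protein uses
its complete cases. A rank-deficient design (batch confounded with group)
is an error listing the aliased columns.

Variance moderation follows the standard moderated-t construction:
with s² ~ s₀²·F(d, d₀) under the hierarchical model, the residuals
e = log s² − ψ(d/2) + log(d/2) satisfy Var(e) = ψ′(d₀/2) + ψ′(d/2), so
the excess of the observed variance of e over the mean ψ′(d/2) term
identifies d₀ through the trigamma inverse (Newton iteration), and the
mean of e identifies s₀². Non-positive excess ⇒ d₀ = ∞ and all moderated
variances equal s₀². Zero sample variances are excluded from estimation
and assigned s₀² afterwards, so degenerate fits cannot poison the moment
matching. The moderated t = β̂/(s̃√v) uses t(d+d₀) (normal when d₀ = ∞);
d₀ = 0 reduces exactly to the ordinary t-test. Benjamini–Hochberg step-up
adjustment is implemented directly (it is part of the tested surface) and
cross-checked against statsmodels in the suite. Significance =
adjusted p < 0.01 AND |log2FC| > 1. Reported fold changes are the model
coefficients, not raw mean ratios; "down-regulated k-fold" means
k = 2^(−log2FC).

## Anomaly diagnostics

Per protein, a maximum-likelihood Gaussian over healthy-donor log2 values
(μ = mean, σ with divisor n; an unbiased-σ flag exists). Stringency
filters, each recorded rather than silent: ≥ 3 peptides, ≥ `n_min` = 20
healthy observations (the reference cohort has 68), and σ > 0.05 log2
units. The σ floor guards against near-constant proteins whose tiny σ
would turn measurement noise into astronomically small probabilities.

A patient value x receives p = 2·Φ(−|x−μ|/σ), the two-sided Gaussian tail
(a one-sided option is exposed). The two-sided form was chosen because
both losses and inductions are diagnostically meaningful and the ranking
is then scale-free in |z|. Probabilities are reported raw (the
inspection cut at 0.01 is a per-protein screen, not a multiplicity-
controlled test); BH-adjusted values can be annotated on request. The
report sorts by increasing probability with deterministic tie-breaking
(|z| descending, then protein id) and floors probabilities at the
smallest positive float so they stay in (0, 1]. Gaussian fits use the
raw log2 matrix by default (flag available), consistent with the
blocking-not-adjusting convention of the testing stages.

Calibration note: for a patient drawn from the *fitted* reference, the
flag probability per protein equals the threshold exactly — this is the
property the acceptance suite measures (20 null patients × ~3 500
proteins; binomial error ≈ 0.0004).

## Batch adjustment (ComBat, parametric)

Standardize each complete-case protein by its size-weighted grand mean
and ML pooled variance about batch means; estimate per-(batch, protein)
locations γ̂ and scales δ̂²; shrink with a normal prior on γ and an
inverse-gamma prior on δ² whose hyperparameters come from moments across
proteins; solve the posterior by fixed-point iteration (relative change
< 1e-6, max 100 iterations, error with trace on failure); back-transform.
Only the parametric variant is implemented, and no group covariate is
given to the standardization: the adjusted matrix serves visualisation
only, and the accepted risk of over-correction in unbalanced designs is
the reason the DE stage never sees it. Rows with missing values bypass
adjustment with a warning; a single-batch input is a no-op; a batch with
one sample is an error instructing merge or exclusion. The implementation
is validated against Bioconductor `sva::ComBat` (atol 1e-3, the gap being
sva's looser 1e-4 convergence).

Idempotence caveat: because EB shrinkage leaves a residual proportional
to estimation noise, a second pass finds batch effects at the noise floor
σ√(2/(πn)) rather than exactly zero; the suite asserts exactly that.

## Profiling

PCA: SVD of the protein-centred matrix (complete-case rows, count
reported); sample scores are right singular vectors × singular values,
variance fractions the normalized squared singular values — verified
against a covariance eigendecomposition oracle at 1e-8. Replicate QC:
all pairwise Pearson coefficients among one subject's samples on shared
observed values. TPM: rate_g = count_g/length_g, TPM = 1e6·rate/Σrate.
Protein–mRNA correlation: Pearson on log2 of per-gene medians (log is the
default; both axes' transforms are flags), ≥ 10 shared positive genes
required. Heatmap: per protein subtract the healthy mean, per sample
z-transform the column, then Euclidean agglomerative clustering on both
axes; the linkage method is a flag with average (UPGMA) as default, since
only the distance is dictated by the visualisation convention. ORA:
one-sided hypergeometric of the foreground/set overlap within the
quantified background (foreground must be a subset; sets are intersected
with the background first), BH across tested sets, sets under the overlap
minimum reported untested; an EASE-style (overlap − 1) variant is a flag.

## Synthetic cohort generator

The generator defines the conditions everything is tested under. Cell
model on the log2 scale:

    x_ps = m_p + gamma[b(s), p] + signature_p(s) + eps,
    eps ~ N(0, delta[b(s)] * sigma_p^2)

with m_p ~ N(mu0 = 20, sd0² = 4), σ_p² ~ d₀s₀²/χ²(d₀) with d₀ = 4,
s₀² = 0.04, γ ~ N(0, τ² = 0.09) per (batch, protein), and per-batch
variance inflation δ ~ Gamma(40, 1/40) (sd ≈ 16%, mild). Defaults: 4154
proteins, 68 healthy donors, 16 patients (6 SCN-ELANE, 5 CGD, 3 LAD, 2
unresolved), 6 processing-date batches with seeded-shuffle round-robin
assignment so batch is never confounded with group.

sd0 = 2 log2 units makes the generated abundances span ≥ 4 orders of
magnitude; the top `top_k_half` = 7 proteins are then rescaled
analytically to hold a hair over half of the total linear abundance
(block sum set to (1+1e-6) × the rest; if proportional scaling would
break the abundance order the block is redistributed above a floor just
over the largest remaining protein, and infeasible configurations raise).
This guarantees the "k proteins hold 50%" count exactly on the true
means; empirical per-sample shares and the molar-mass division of the
ruler wobble around 50%, which is why the concentration benchmark is
measured on the true means.

Disease signatures are fixed log2 offsets on named marker proteins
(e.g. CYBA −log2 16, CYBB −log2 84, RAB27A −log2 100, NCF1 −5), not
resampled, so fold-change recovery has a known target; callers can
register custom signatures. Peptide support is 1 + Poisson(a + b·m_p)
(a = −6, b = 0.5), a qualitative "more peptides for abundant proteins"
link whose exact form is a free choice. Replicates of a subject share the
subject's realized profile and differ by technical noise with
sd = 0.78 log2 units, derived in closed form from
r = Var(profile)/(Var(profile)+sd²) with Var(profile) ≈ sd0² + E[σ²] =
4.08 so the expected same-subject Pearson correlation is 0.87. RNA
counts are negative-binomial with log-means correlated ρ (default 0) with
the standardized protein means; generator streams are seeded disjointly
from the cohort stream so ρ = 0 really is independence. Data are complete
by default with an optional MCAR switch; the generator does not model
DIA-specific intensity-dependent missingness, spectra, or retention time.

What passing tests therefore show: the statistical machinery is correct
under its own assumptions (Gaussian log-intensities, shared variance
prior, location/scale batch effects, fixed offsets). What they do not
show: robustness to non-Gaussian tails, informative missingness, or
peptide-level interference in real DIA data.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the measured quantities are stable: calibration
at 4 000 proteins × 68 donors × 20 null patients; knockdown recovery at
2 000 × 68 over 20 seeds; variance-prior recovery at 5 000 proteins with
70 df; DE error control at 2 000 proteins, 6 cases vs 68 controls, 10
seeds for each of the null and signal rounds; ComBat recovery at 3 000
proteins × 60 donors. Seeds are fixed in tests and derived from `--seed`
in the script; all generator streams are PCG64. Tolerances follow the
quantity's own sampling error (e.g. the calibration band 0.010 ± 0.003 is
> 8 binomial standard errors wide; eBayes recovery within 15%).

## Known limitations

- One contrast per DE run; no random-effect replicate modelling or
  time-course designs; no peptide-to-protein roll-up.
- ComBat is parametric-only and covariate-free.
- The anomaly model is univariate per protein; correlated co-regulation
  (e.g. a whole granule compartment shifting) is surfaced only as many
  single-protein flags, not modelled jointly.
- The ruler assumes diploid DNA content and histone-signal fidelity;
  aneuploid or histone-degraded samples bias all copy numbers in that
  sample.
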