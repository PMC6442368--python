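# granudx

Quantitative neutrophil-granulocyte proteome analytics for rare-disease
diagnostics: absolute copy numbers per cell, batch-blocked differential
protein expression, and — the centrepiece — a cohort-referenced Gaussian
anomaly detector that ranks a single patient's proteins by how incompatible
each level is with a healthy reference cohort.

**Who it is for.** Groups running DIA (data-independent acquisition)
proteomics on purified blood cells across clinical cohorts — e.g. severe
congenital neutropenia (SCN), chronic granulomatous disease (CGD), or
leukocyte adhesion deficiency (LAD) — who want to turn a protein × sample
intensity matrix into (a) interpretable copy numbers, (b) per-disease
differential signatures, and (c) a per-patient shortlist of candidate genes
when exome sequencing is inconclusive. Loss of NCF1 protein points to
*NCF1* pseudogene-masked mutations; loss of RAB27A points to Griscelli
syndrome type 2 — the detector's z-ranking surfaces exactly such candidates.

## The methods in brief

**Proteomic ruler.** Histones are stoichiometric with DNA (~6.5 pg per
diploid cell), so per sample

&nbsp;&nbsp;mass_p = m_DNA · I_p / Σ_{h∈histones} I_h, &nbsp; copies_p = mass_p · N_A / MW_p.

**Differential expression.** Per protein, OLS of log2 intensity on group +
processing-date batch (blocking, not ComBat). Residual variances s²_p with
d_p df are shrunk toward a scaled inverse-chi-square prior (d₀, s₀²)
estimated by moment matching on log s²; the moderated statistic
t_p = β̂_p / (s̃_p √v) with s̃²_p = (d₀s₀² + d_p s²_p)/(d₀+d_p) is referred
to t(d_p+d₀); Benjamini–Hochberg control at adjusted p < 0.01 with
|fold change| > 2.

**Anomaly diagnostics.** Per protein (≥3 peptides, ≥20 healthy values),
a maximum-likelihood Gaussian (μ_p, σ_p) over healthy donors; a patient
value x gets probability p = 2·Φ(−|x−μ_p|/σ_p), and proteins are reported
in increasing-probability order with p < 0.01 flagged for inspection.

**Cohort profiling.** Parametric ComBat (location/scale empirical Bayes)
for PCA and healthy-referenced z-score heatmaps with Euclidean hierarchical
clustering; TPM from counts and exon-union lengths; hypergeometric gene-set
over-representation against the quantified background.

**Synthetic cohorts.** A generator with full ground truth reproduces the
statistical structure all of the above assumes (68 healthy + 16 patients,
heavy-tailed abundances with the top 7 proteins holding half the total,
inverse-chi-square protein variances, per-batch location/scale effects,
fixed disease signatures such as a 84-fold CYBB knockdown, replicate
correlation ≈ 0.87, RNA counts decoupled from protein). Every analysis
stage is tested against this truth.

## Worked example

```bash
python examples/01_simulate_and_diagnose.py
```

prints (abridged):

```
healthy reference: 3617 proteins (537 excluded by stringency filters)

PT15: 38 proteins with probability < 0.01
  NCF1     z= -12.5  p=9.11e-36  (underexpressed)
  ...
PT16: 39 proteins with probability < 0.01
  RAB27A   z= -22.2  p=1.47e-109  (underexpressed)
```

PT15 and PT16 are the two simulated patients without a genetic diagnosis;
the detector ranks the causal protein first in both, with ~40 of 3617
proteins (≈1%) below the 0.01 threshold — the nominal false-flag rate, so
nearly everything else on the shortlist is the expected background. The
other examples cover differential expression (`02`), copy numbers (`03`)
and cohort profiling (`04`). The same stages are scriptable via the
`granudx` CLI (`simulate`, `preprocess`, `ruler`, `diffexp`, `diagnose`,
`profile`, `enrich`, `run`).

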