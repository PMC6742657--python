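# Methods

`mechanoprot` quantifies how cells — in the motivating application, primary
human mesenchymal stem cells subjected to cyclic tensile strain — respond to a
treatment at the protein, PTM-site and pathway level, starting from
label-free peptide-ion intensity tables of the kind exported by MS alignment
software. This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Ingestion and preprocessing

Peptide tables are CSV, one row per peptide ion, with modification
annotations encoded `offset:label` (offsets are 1-based within the peptide).
Empty intensity cells are treated as *missing*, never as measured zeros: ion
non-detection in label-free MS is censoring. Three preprocessing steps mirror
common practice:

1. **Identification-confidence filter.** Mascot-style scores are mapped to
   per-peptide p-values by the defining identity p = 10^(−S/10),
   Benjamini–Hochberg adjusted across the table, and peptides with
   q ≥ 0.2 (default) are removed.
2. **Peptide-count filter.** Proteins with fewer than 3 distinct unique
   peptide sequences (default) are removed entirely; shared
   (non-unique) peptides never count and are also excluded from model
   fitting.
3. **Normalization.** Intensities are log2-transformed and each sample's
   median is subtracted, so every sample has median 0 on the log scale.
   Everything downstream reads in log2 units.

The filter order is confidence first, then peptide count (configurable):
confidence filtering can only lower peptide counts, so this order is the
conservative one.

PTM sites are localized by leftmost exact substring match of the peptide in
its protein; multiple matches flag the annotation ambiguous, and ambiguous
sites are excluded from site-level reporting by default (emitted to a side
table). The registry of searched modifications carries the monoisotopic mass
deltas used in the source experiments (carbamidomethyl 57.021 Da on C,
oxidation 15.995 on M, hydroxylation 15.995 on N/D/P/K, phosphorylation
79.966 on S/Y/T/H/D, monobromobimane 133.053 and 150.056 on C).

## The per-protein model

For each protein, log2 peptide-ion intensities are modeled as

    y_fgd = β0 + Xf βf + Xg βg + Xd βd + XfXg β_fg + XfXd β_fd + ε,
    ε ~ N(0, σ²/w),

where f indexes peptide ions, g treatment groups and d donors. Peptides and
donors are coded sum-to-zero; treatment is coded against the reference group,
so **β_g is directly the protein's log2 fold change versus the reference**.
The peptide×treatment interaction β_fg carries differential behavior of
individual peptides — for a modified peptide, the fold change in site
occupancy (the modified fraction of the protein pool). Rows exist only for
observed intensities; no imputation is performed. Single-donor designs drop
the donor terms.

### Prior structure

The fit is a Bayesian elastic net sampled by Gibbs, written in the Gaussian
scale-mixture form β_j ~ N(0, σ²/(τ_j⁻¹ + λ2)) with τ_j ~ Exp(λ1_j²/2).
Three structural choices matter, all driven by the scale heterogeneity of the
coefficient groups:

- **Penalties are block-structured** (peptide, treatment, donor, and the two
  interaction blocks). Ionization effects span whole log2 units while most
  interactions are null; a single global penalty lets the large block set the
  scale and visibly biases treatment effects.
- **The L1 component is the adaptive Bayesian lasso**: every coefficient has
  its own λ1_j² with a Gamma(1, 1) hyperprior. Strongly supported effects
  escape shrinkage; null coefficients stay pinned. This applies to the
  peptide, treatment and donor blocks.
- **Interaction blocks get ridge only, and the peptide×treatment ridge is a
  small fixed constant** (λ2 = 0.01 by default, `McmcConfig.interaction_ridge`).
  Two reasons. First, in sum-to-zero coordinates a single-peptide occupancy
  shift makes *every* coefficient of the block nonzero, so L1 sparsity is
  expressed in the wrong basis and biases occupancy estimates toward zero.
  Second, these coefficients are reported effect sizes: an adaptive ridge —
  correct under exchangeability — shrinks the few large (modified-peptide)
  coefficients toward the block's many small ones and so biases occupancy
  fold changes downward. The fixed weak ridge keeps the posterior proper
  under rank deficiency (missing cells can zero out interaction columns) at
  negligible bias — the occupancy-recovery benchmark measures the residual
  bias directly. The peptide×donor block
  keeps an adaptive ridge: donor wobble is genuinely dense and zero-centered,
  and those coefficients are never reported.

λ2 for adaptive blocks uses the usual Gamma(a2 + p_b/2, b2 + Σβ²/(2σ²))
conditional, ignoring the normalization coupling through the scale mixture
(the standard simplification). σ² has an InvGamma(1e-3, 1e-3) prior; the
intercept is unpenalized.

### Confidence-weighted residuals

At every Gibbs iteration, observation weights are recomputed from the current
standardized residuals r and the identification score S:

    w = qc + (1 − qc) · 1/(1 + (r/c)²),   qc = 1 − 10^(−S/10) (clipped to [0,1)),

with c = 3 standardized residuals by default. A high-confidence observation
(qc → 1) keeps weight ≈ 1 no matter how outlying it is — its contribution is
not diminished — while a low-confidence outlier is down-weighted by a Cauchy
kernel. The weight multiplies the observation's precision in the likelihood.
`robust_weighting=False` forces all weights to 1 (used for the
least-squares-limit validation).

### Chains, estimates, diagnostics

Default chains run 4,000 iterations with 1,000 burn-in (no thinning); batch
experiments in the test suite use 1,000–2,000 iterations, which the
validation results show is sufficient for these small designs. Posterior
*means* are Rao-Blackwellized (the average of the per-iteration conditional
means E[β | rest]), which removes most Monte-Carlo noise from reported
effects; posterior sd and the coefficient covariance (used for contrasts)
come from the draws. Monte-Carlo SE is estimated by batch means on the
conditional-mean sequence. Convergence is monitored by split-R̂ on each β_g;
values above 1.1 flag (never discard) the protein. Identical seeds give
bit-identical results; the per-protein seeds in batch runs derive
deterministically from the run seed.

## Moderated inference

Per-protein residual variances s² (posterior mean of σ², with residual df
n − rank(X)) are shrunk by empirical Bayes: a scaled inverse-χ² prior
(d0, s0²) is moment-matched on log s² using the digamma/trigamma identities
(trigamma inverse by Newton), and each protein's variance becomes
s̃² = (d0·s0² + d·s²)/(d0 + d). The moderated t-statistic scales the
posterior se of β_g by s̃/s and is referred to a t distribution with d0 + d
degrees of freedom, two-tailed. With fewer than 10 proteins or no variance
spread the procedure falls back to no moderation (d0 = 0), logged. BH
adjustment is applied across all proteins × contrasts of a batch.

The BH step-up itself is implemented directly from its definition
(q_(i) = min_{j≥i} p_(j)·n/j, capped at 1) so adjusted values agree exactly
with a brute-force transcription; the test suite also cross-checks against
statsmodels.

## PTM site occupancy

The occupancy log2 fold change of a site is estimated as the contrast between
the interaction effects of the peptides carrying the modification and the
protein's *unmodified* peptides (the baseline population that tracks total
protein). Under sum-to-zero coding, the raw β_fg of a modified peptide
absorbs only (F−1)/F of the occupancy shift — the treatment term takes the
rest — so the contrast, not the raw coefficient, is the unbiased estimate.
When several peptide ions cover one site (overlapping sequences, charge
states), their contrasts are combined by inverse-variance weighting using the
posterior covariance. p-values use the protein's moderated variance scaling;
BH runs across all sites. Contrast variances come from the full posterior
covariance of the coefficient vector, so correlations between interaction
coefficients are accounted for.

## Pathway model

Pathway effects are fitted on per-protein log2 fold changes:

    y_gp = βg + βp + ε,

with sum-to-zero protein effects and cell-means coding for groups. Because
the responses are already fold changes versus the reference condition, the
intercept is absorbed into the group effects: β_g is directly the
pathway-level log2 fold change in group g and is tested against 0 (two-tailed
t from the least-squares fit). Estimation is ordinary least squares — the
responses are model outputs without per-observation identification scores, so
the confidence-weighting machinery has nothing to act on. Pathways with fewer
than 3 quantified members are dropped; BH runs across all pathway × group
tests. Proteins missing a fold change in any group are excluded from that
pathway's fit.

## Distribution-level summaries

- **Gaussian fits to fold-change histograms**: fixed bin width (default 0.1
  log2 units), nonlinear least squares of A·exp(−(x−μ)²/2σ²) on bin counts,
  initialized at the sample mean/sd and max count. The headline "width" is
  the fitted σ; FWHM (2.355σ) is also reported, along with the fit RMSE as a
  lack-of-fit indicator.
- **Transcript centering**: per-gene log fold changes are median-centered,
  under the assumption that most genes are unperturbed.
- **Transcript–protein correlation**: squared Pearson correlation of paired
  log2 fold changes; the join key between gene and protein identifiers is
  caller-supplied, not hard-coded.
- **Time-course clustering**: K-means (configurable restarts) over proteins ×
  timepoints, with the cluster count selected by mean Euclidean silhouette
  over a candidate range. Proteins with missing timepoints are dropped, not
  imputed. All-identical input degenerates and is flagged rather than
  clustered.

## Per-cell imaging statistics

Morphometric measures (nuclear area, cytoplasmic area, envelope intensity,
texture, γH2AX intensity) are modeled per cell as y_gd = β0 + Xg βg + Xd βd + ε
with treatment against reference and donors sum-to-zero, fitted by OLS;
p-values are the standard two-tailed t-tests. The fit consumes values as
given; `normalize_to_control` (divide by the donor's control-group mean, then
log2) is the provided preprocessing that makes β_g read as a log2 fold
change. Complete confounding of donor with group raises an error naming the
confounded group. Ratios (e.g. nuclear:cytoplasmic area) are per-cell derived
measures; cells with a zero denominator are excluded and logged. Power-law
scaling between expression and a measure is the slope (± standard error) of a
simple linear regression in log2–log2 space, on per-cell points or on
per-condition means (`condition_means`) — both modes are exposed because
either aggregation is defensible.

## Synthetic data

`simulate_proteomics` is the generative mirror of the per-protein model:
protein baselines N(25, 2²) log2 units, peptide counts triangular (3, 5, 30),
ionization effects N(0, 1.5²), donor effects N(0, 0.2²) at the protein and
N(0, 0.1²) at the peptide level, residual sd 0.3 log2, 3 donors, one control
and one strained condition, 20% differential proteins with |β_g| uniform in
[0.5, 1.5] log2 and random sign, 5% of peptides carrying a phosphosite with a
+1 log2 occupancy interaction, 10% missing cells (completely at random by
default; an intensity-dependent left-censoring mode is available since real
LFQ missingness is left-censored). Identification scores are
intensity-correlated — 15 + 5·z(mean log2 intensity) + N(0, 3), floored at
1 — because the confidence weighting is only meaningful if scores vary with
signal quality. Generated protein sequences are concatenations of the
peptides, so site annotation round-trips exactly. Generators are pure
functions of config + seed.

What the simulations do **not** emulate: shared peptides between proteins,
retention-time or alignment artifacts, isotope interference, and
intensity-dependent variance. Passing the benchmarks therefore shows the
estimators are correct and calibrated under the model's own assumptions, not
that those assumptions hold for any particular instrument.

### Benchmark scenarios (`mechanoprot.benchmarks`)

Problem sizes are chosen to give stable rates at desk scale: 50 random
designs for the least-squares limit, 200 proteins for effect recovery,
20 × 300 proteins for null calibration, 100 replicates for occupancy
recovery, 50 replicates for pathway detection (1 shifted + 19 null pathways
each), 100 seeds for cluster-count selection. Two scenarios fix their noise
levels by what the check is for: the occupancy scenario (8 peptides, site
covered by 2 ions, residual sd 0.1) and the imaging-recovery scenario
(per-cell sd 0.25) use low noise so their ±0.2 and ±0.05 bands measure
estimator *bias* rather than sampling noise — at the generators' default
noise the sampling error alone would exceed the bands for any unbiased
estimator. Effect-recovery and calibration scenarios run with the PTM
interaction disabled so that β_g truth is not contaminated by occupancy
signal (a +1 shift on one of F peptides moves the protein consensus by 1/F).

## Known limitations

- Protein inference/grouping from shared peptides is out of scope; shared
  peptides are simply excluded from fitting.
- The weighting function satisfies the qualitative contract (high-confidence
  outliers keep full weight) but is a package-defined form; it is isolated
  behind `compute_observation_weights` so it can be swapped.
- Under heavy missingness a peptide×group cell can vanish entirely; the fit
  remains proper (the interaction ridge floor) but that interaction is then
  prior-dominated with an honestly wide posterior.
- Moderation treats the posterior-mean σ² as a sampling variance with
  n − rank(X) df, which is an approximation for a Bayesian fit; the null
  calibration benchmark shows the resulting tests are conservative.
- K-means cluster-count selection by silhouette is one defensible criterion
  among several; the selection scores for all candidate k are returned so a
  caller can apply another rule.
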