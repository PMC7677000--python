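# Methods

## Scope and data model

The package starts at the feature table: a features × samples matrix of
positive linear intensities per ion mode, with per-feature m/z, retention
time (s) and mode, and a sample → group map over
{LB, QC, B108, B253, B263, B313, B424, B505, B585}.  Raw-spectrum peak
picking, retention-time alignment and MS/MS fragment matching are out of
scope; the feature identifier `M<mz>T<rt>` encodes the nominal
(round-half-up) m/z and retention time.

## Pre-screening hygiene

*QC filtering.*  A feature is kept when its relative standard deviation
(sample SD, n−1 denominator, over mean) across pooled-QC injections is
≤ `max_qc_rsd` (default 0.30) **and** it is present in at least
`min_presence_fraction` (default 0.5) of the biological samples.  Both
cuts are the community's conventional defaults; the original analysis
does not state its "high-quality feature" criterion, so these are
configurable.  The filter is idempotent and monotone in its thresholds.

*Imputation.*  Absent values become half the feature's minimum observed
intensity — simple, monotone, and safely below every observed value.
Features absent everywhere are dropped with a warning.

*Normalization.*  Each sample is rescaled so its total (or median)
intensity equals the across-sample mean of that statistic.  The pipeline
default is **median** normalization: with a handful of strongly induced
features, total-intensity scaling transfers their signal into every other
feature of the same samples and biases both fold changes and PLS-DA
weights, whereas the median is insensitive to a few large features.

## Multivariate screening

All multivariate work is done on log10 intensities, column-centered and
(by default) unit-variance scaled.  PCA is the SVD of that matrix with a
deterministic sign convention (largest-magnitude loading per component
made positive).  PLS-DA uses NIPALS for a univariate 0/1 class response:
per component, the weight vector `w ∝ X'y` (unit norm), scores `t = Xw`,
loadings `p = X't/t't`, `q = y't/t't`, followed by deflation of X and y.
Per-component explained response variation is `SS_a = q_a² · t_a't_a`, and

VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),

so mean(VIP²) = 1 by construction.  The default model size is 2
components — enough for a two-group contrast while keeping the VIP
denominator stable; it is configurable.

*Permutation diagnostic.*  Q² = 1 − PRESS/TSS by stratified K-fold
cross-validation (K = 7, reduced to the smaller class size when needed,
folds fixed by the seed).  For each of ≥ 20 label permutations the model
is refit and (R², Q², |corr(y_perm, y)|) recorded; the original point
enters the Q²-vs-correlation regression at correlation 1.  The model
passes when every permuted Q² is below the original and the regression
intercept is negative.  Note that with a single informative feature among
many noise features at n = 12, an honestly cross-validated Q² is small —
two-class LC-MS contrasts pass because many correlated features separate
the groups.

## Candidate cascade

Per strain and ion mode: step I keeps features with linear
mean(strain)/mean(LB) ≥ 2, Welch-t p < 0.05 on log10 intensities, and
VIP ≥ 2 from the strain-vs-LB model.  The strain's step-I set is merged
(stable order) with the control strain B313's own step-I set, and step II
retains union features with mean(strain)/mean(B313) ≥ 10, p < 0.05 and
VIP ≥ 2 from the strain-vs-B313 model.  Ratios use arithmetic means of
linear normalized intensities (matching the magnitude of published fold
changes); p-values use the log10 scale for variance stabilization.  Raw
p-values are reported by default (a Benjamini–Hochberg option exists but
is off), matching the source analysis.  The candidate set is monotone in
all four thresholds.

## Annotation

Expected adduct m/z is the monoisotopic mass ± 1.007276 Da
([M+H]⁺ / [M−H]⁻ only); a feature is annotated when
|observed − expected|/expected ≤ 10 ppm.  Library masses are recomputed
from molecular formulas at load time and cross-checked against the stored
values.  Compounds flagged as common microbial nutrients (L-tyrosine,
L-sorbose, L-leucine, L-valine) are excluded before bioassay follow-up.
Candidates are deduplicated by CAS across strains and modes; rows with
several equally close matches are kept and flagged ambiguous.

## In-situ quantification

per_larva_mass = extract_conc × extract_volume / n_larvae (defaults
1.5 ml, 20 larvae); surface_concentration = per_larva_mass /
(water_mass_mg × 10⁻⁶ liter/mg), with the cuticular water film fixed at
0.0920 mg and water density taken as 1 g/ml.  Both maps are linear and
exactly invert the synthetic generator at zero noise.

*Group comparison.*  Both groups normal → Student t (equal variances by
Levene, mean-centered) or Welch t; otherwise Mann–Whitney U with the
normal approximation and tie correction.  The normality screen is the
plain one-sample Kolmogorov–Smirnov test against a normal with the
sample's fitted mean/SD (as SPSS's NPAR procedure computes it).  This
uncorrected variant is deliberately conservative: with 5–9 dose groups
screened jointly, a Lilliefors-corrected test would false-reject joint
normality in roughly a quarter to a third of null datasets and push
normal data onto the nonparametric branch; the conservative screen keeps
parametric branches for normal data while still catching strong skew
(lognormal σ = 3 data is rejected in ≥ 95 % of runs at n = 15).  The
Lilliefors variant remains available (`method="lilliefors"`).  Groups
with zero variance go to the nonparametric branch with a warning.

## Cocktail and bioassays

The recipe copies each detected metabolite's group-mean concentration
verbatim and includes it when that mean is ≥ 0.1 mg/liter; below-detection
metabolites are always excluded.  This threshold reproduces the published
7-component formulation (trace hypoxanthine at 0.001 mg/liter and
undetected ethylmalonic acid stay out; kynurenic acid at exactly
0.1 mg/liter stays in) and is configurable.  Doses are 2¹ … 2⁻⁶ times the
recipe plus an all-zero control.

Relative rates are 100 × mean(treatment)/mean(control); mycelial growth
first subtracts the 3-mm inoculation plug from every colony diameter so
the rate measures net extension (the source protocol does not state
whether the plug is subtracted; net growth is the dimensionally sensible
choice).  Omnibus comparison follows the same normality screen: all
groups normal and Levene-homogeneous → one-way ANOVA with Tukey HSD;
normal but heteroscedastic → Welch's ANOVA (hand-implemented from the
standard formula, cross-checked against pingouin) with pairwise Welch
comparisons adjusted Šidák-style over the number of pairs (the practical
form of Dunnett's T3); any normality failure → Kruskal–Wallis with
Bonferroni-corrected pairwise Mann–Whitney.  Group letters come from the
insert-and-absorb compact-letter-display algorithm.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the package's test suite verifies them against a hand
tabulation of observed-minus-expected deaths and hypergeometric variances
at each shared event time.  Ties follow the standard convention (all
deaths at a time counted against that time's risk set; censoring at an
event time processed after the event); subjects surviving to pupation are
censored at the last observation day.  A comparison with no events (or
zero total variance) degrades to χ² = 0, p = 1 with a warning.

## Synthetic data

The generators emulate the study design: per ion mode, log10-normal
intensities with a per-feature baseline (spread 0.5 log10 units around a
mean of 6), six replicates per group, pooled-QC samples equal to the
per-feature grand mean of the biological samples perturbed by
multiplicative noise (σ = 0.05 log10 by default), and uniform missingness
(default 2 %, never in QC columns of planted features).  A planted
candidate multiplies its target strains' means by `fc_vs_lb` and sets
B313's mean so that strain/B313 equals `fc_vs_b313`; arithmetic-mean
ratios are unbiased for these fold changes because the log-normal noise
term cancels.  Planted candidates carrying a CAS found in the packaged
library receive that compound's adduct m/z (sub-ppm jitter), so
annotation resolves end to end.  Quantification data invert the surface
conversion exactly and add multiplicative noise of a given CV; bioassays
draw binomial germination counts (100 conidia, control rate 0.8) and
normal colony diameters (control 43 mm, plug 3 mm); survival times are
exponential, recorded on a 2-day grid and censored at the horizon
(14 days).  Dispersion defaults are free parameters (the source reports
none); they were fixed once at values typical for culture-supernatant
LC-MS and are documented in `SimFeatureConfig`.

What the simulations do **not** model: chromatographic peak shape,
RT drift, batch effects, isotope patterns, intensity-dependent
(MNAR) missingness, or between-feature correlation.  Passing tests
therefore demonstrate the correctness of the statistical machinery under
the stated model, not robustness to those real-data artifacts.

## Problem sizes and numerics

The default test battery uses 200-feature tables for recovery runs (50
seeds), 500 simulations for type-I-error checks, and ≤ 8 × 8 instances
for algebraic oracle comparisons (tolerance 1e-6 to 1e-8).  NIPALS stops
components when residual covariance falls below 1e-12; zero-variance
features are dropped with a warning before scaling; the conservative
guards (zero control mean, zero Y-variance, empty recipes) raise typed
errors rather than propagating NaNs.
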