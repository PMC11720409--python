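# Methods

## Problem setting

Two affinity proteomics platforms quantify overlapping protein panels in
the same CSF cohort: an aptamer platform run twice independently (runs A
and B, raw linear RFU) and an antibody/PEA platform run once (log2 NPX).
The pipeline asks three questions: (1) which reagents reproduce within the
aptamer platform and across platforms, (2) how technically precise each
platform is (calibrator CVs), and (3) whether filtering association
screens to reproducible reagents concentrates biological signal.

## Harmonization

Each dataset is harmonized independently: linear RFU values are
log2-transformed, then every reagent row is centered and scaled to unit SD
(n−1 denominator) across samples.  Constant rows have no z-score and are
dropped with a logged reason; they are excluded from all correlation and
association stages.  Because every downstream correlation is rank-based,
z-scaling never changes a Spearman ρ — the tests assert this invariance
explicitly — but it standardizes effect sizes (betas per SD of protein)
and is required by the PCA and regression stages.

## Reagent pairing

Reagents match across datasets when their UniProt accession *sets* are
equal.  Protein complexes annotated with several accessions match only on
the complete set; a single-accession reagent never pairs with a complex.
Pairing is many-to-many (several aptamers per protein × several antibody
subpanel assays per protein), so counts are reported both at pair level
and collapsed to unique UniProt-ID-set level.

## Coefficients of variation

CVs use the raw, pre-harmonization matrices and only calibrator samples.
Intra-assay: per plate, the CV over that plate's calibrators, averaged
unweighted across plates (plates with fewer than two calibrators are
skipped).  Inter-assay: a single CV over all calibrators pooled across
plates.  The formula follows the readout scale:

* linear RFU: CV = σ/μ (sample SD over mean);
* log2 NPX: CV = √(exp((ln 2 · σ_NPX)²) − 1), the log-normal CV identity
  after converting the base-2 log-SD to natural log.  This form has the
  right limits (CV → 0 as σ_NPX → 0, monotone increasing) and is invariant
  under additive NPX shifts, as a CV of a log-scale readout must be.

Percentile summaries use linear interpolation; distribution comparisons
use a two-sided Mann-Whitney U test after trimming CVs beyond 1.5×IQR.

## PCA and outliers

PCA runs on the harmonized matrix with samples as observations (reagent
columns are already centered by the z-scaling).  Per-component sign is
fixed by making the largest-magnitude loading positive, so results are
deterministic across SVD implementations.  PC–phenotype screens come in
two modes: marginal Pearson correlations per (PC, variable), and a joint
linear model of each PC score on all variables simultaneously.  Sample
outliers are those whose PC1 or PC2 score lies outside 1.5×IQR of the
quartiles; the component set and fold are configurable because the choice
of screened quantities is genuinely open.

## Reproducibility score

Spearman ρ (average ranks for ties, pairwise-complete observations, a
minimum of 10 overlapping samples by default) is categorized as good
(ρ ≥ 0.5, boundary inclusive), moderate (0.3 ≤ ρ < 0.5) or poor (ρ < 0.3,
negative correlations included — the classification does not treat them
separately).  The intra category (same aptamer across runs A and B)
crossed with the best inter category gives scores 1–9; aptamers without
any antibody match receive A–C from the intra category alone.  When an
aptamer has inter records against both runs, or several antibody subpanel
matches, the record with the highest ρ decides — the max-ρ rule is applied
across all candidates.  Scores 1–3 and A define the reproducible set.
Cross-run pairing of *different* aptamers targeting the same protein is
deliberately not performed for the intra record.

## Association screens

For a continuous trait the model is OLS with the z-scored protein as
outcome and the trait plus covariates as predictors; the reported beta is
the change in protein (SD units) per unit of trait, with a two-sided Wald
p.  For sex the model is logistic with sex as outcome and the protein as
predictor (a configurable orientation: the natural adjustment story reads
protein levels adjusted for total protein and technique, while sex only
works as an outcome).  Covariates are sex, age and CSF total protein, plus
assay technique for the two CSF biomarkers (Aβ42, p-tau); a covariate
equal to the tested phenotype is dropped.  t-tau is never screened — it is
nearly collinear with p-tau.  Rankings sort by ascending p with ties
broken by descending |beta| then reagent id, making top-K sets
reproducible.  The Bonferroni flag uses alpha divided by the number of
reagents tested.

The LASSO evaluation makes one 80/20 split (stratified for binary
outcomes), tunes the L1 penalty on the training part by 5-fold CV repeated
5 times over a 100-point log-spaced grid spanning four decades below the
data-derived maximal penalty (the smallest penalty that zeroes all
coefficients), selecting by RMSE (continuous) or AUC (binary), and reports
the held-out R² or AUC/sensitivity/specificity.  Everything is
deterministic under the seed.

## Top-K overlap and its bootstrap null

The observed statistic is the intersection of the top-K (default 500)
reagent ids across m phenotype rankings, at reagent level (a unique-protein
collapse is reported alongside).  The null: per iteration draw m multisets
of K uniform with-replacement draws from the N-reagent universe, reduce
each to its unique elements, intersect.  Reducing to unique elements before
intersecting is the construction whose expectation matches the closed form
E = N·(1 − (1 − 1/N)^K)^m (2.125 for N = 7289, K = 500, m = 3; 15.66 for
N = 2428), which the tests use as an independent cross-check.  The
empirical p-value is (#{sim ≥ observed} + 1)/(B + 1), so B = 10,000
iterations with zero exceedances gives p < 1 × 10⁻⁴ rather than zero.

Enrichment of hits between two reagent sets uses the 2×2 odds ratio with a
log-OR normal-approximation 95% CI and a Pearson chi-square without
continuity correction; the Haldane–Anscombe +0.5 correction is applied to
all cells, and flagged, only when a cell is zero.  The operation takes
explicit counts because more than one table construction is defensible;
the pipeline default is (hits in reproducible set, reproducible set size)
vs (hits in complete set, complete set size).

## Synthetic study generator

The generator emulates the statistical structure the pipeline assumes, not
any vendor's chemistry.  Per (sample, protein) a unit-variance latent
level carries planted linear phenotype effects (β per SD of trait, entered
at the protein so both platforms inherit the same biology).  Each reagent
reads its target with fidelity α ∈ [0, 1]:

    y = b_r + α·L + √(1 − α²)·e + δ_plate,

log2 scale, so the expected Pearson correlation between two reagents of
fidelities α₁, α₂ is α₁·α₂ and the expected Spearman follows the
bivariate-normal identity (6/π)·asin(α₁α₂/2) — the closed-form oracle the
tests use.  Fidelity is drawn from a two-class mixture (good: uniform on
(0.75, 0.95); poor: uniform on (0.0, 0.25)), shared between the two
aptamer runs (same physical reagent) and drawn independently per protein
for the antibody panel — this reproduces the bimodal correlation
histograms and the fact that internally reproducible aptamers need not
replicate cross-platform.  Calibrator columns share one fixed latent
vector and carry only a per-(reagent, plate) shift ~ N(0, τ_inter) plus
replicate noise ~ N(0, σ_intra), so their CV reflects technical noise
only.  Aptamer matrices are exported as 1000·2^y (an arbitrary positive
baseline documented here), the antibody matrix as y.

Key defaults, chosen once: 264 samples (the cohort size the clinical
marginals were taken from: mean age 71.0 ± 8.28 truncated above 40, 55.7%
female, 230/264 MCI, ~72% ELISA, MMSE and Aβ42/p-tau per
diagnosis-technique cell); f_good = 0.33 (roughly the observed fraction of
internally reproducible aptamers); 16 plates × 2 calibrators; σ_intra =
0.07 and τ_inter = 0.12 log2 units, giving single-digit-percent intra CVs
with inter > intra; antibody panel covering 30% of proteins; 5% of
proteins as two-accession complexes; a 30-protein signature carrying
simultaneous p-tau (+0.5), Aβ42 (−0.4) and MMSE (−0.3) effects as the
substrate for the overlap-enrichment property.  All are overridable
through `SimulationConfig`.

What the generator does *not* emulate: vendor normalization artifacts,
limit-of-detection censoring, missing-not-at-random dropout, batch
bridging, and the hypothesized albumin–aptamer interference (no
quantitative model exists to copy, so none is invented; the fidelity
mixture stands in for all causes of poor reproducibility).  Passing tests
therefore show the pipeline's statistical machinery is correct under the
assumed structure, not that any particular real platform meets it.

## Numerical choices and problem sizes

SD uses the n−1 denominator throughout.  Score assignment is a pure
function of categories, asserted against the exhaustive 12-case truth
table.  Validation runs use desk-scale problems chosen for statistical
adequacy: planted-class recovery uses 300 samples × 3,000 aptamers (the
expected Spearman of the worst good-class reagent, ~0.54, sits several
standard errors above the 0.5 boundary at n = 300, so ≥95% recovery is
expected by construction); null calibration uses 400 reagents × 264
samples; bootstrap nulls always run the full 10,000 iterations, which take
seconds.

## Known limitations

* The linear/logistic orientation question (protein as outcome vs
  predictor) is resolved by convention, not by the data; both orientations
  agree asymptotically on the t-statistic for a single-predictor model but
  not exactly with covariates.
* Spearman p-values are not computed; categories are point estimates of ρ,
  and reagents near a category boundary can flip under resampling.
* Complete-case analysis only; no imputation of missing phenotypes.
* The enrichment 2×2 table construction is parameterized rather than
  canonical; consumers should report which construction they used.
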