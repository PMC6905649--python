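# Methods

This note documents the statistical models the package implements, the
design choices made where conventions genuinely diverge, and what the
synthetic-data generator does and does not emulate.

## Phenotype model

Facial shape is represented by 13 named 3D landmarks per individual. Raw
configurations carry nuisance variation — position, orientation, and global
size — that generalized Procrustes analysis (GPA) removes: each
configuration is centered, scaled to unit centroid size, and rotated onto
the running consensus by orthogonal Procrustes; the consensus is the
normalized mean of the rotated configurations and iteration stops when its
change falls below `tol` (default 1e-10). Two conventions are fixed
deliberately: rotations are proper (det +1) — allowing reflections would
superimpose mirror-image faces — and the initial consensus is the mean of
the centered/scaled inputs, so the result does not depend on sample order.
Distances are reported, by default, on the mean-centroid-size scale
(aligned unit-size shapes multiplied by the sample-mean pre-scaling
centroid size), which keeps them commensurate with the raw coordinate
units and makes simulated effect sizes recoverable on the phenotype scale.

The 78 = C(13,2) inter-landmark Euclidean distances are the phenotypes.
Outliers beyond `outlier_sd` (default 3) standard deviations of their
column are masked in a single pass (no re-masking after the mean/sd
update; masking cells rather than dropping whole samples preserves the
other 77 measurements of an individual). Shapiro–Wilk normality statistics
are reported but never used for filtering. Covariate adjustment regresses
each phenotype on sex, age, and any genotype PCs supplied, keeping
complete-case OLS residuals. Phenotype correlations are Pearson on
pairwise-complete observations; the clustering tree uses 1−|r| with the
Lance–Williams average-linkage recurrence (scipy's agglomeration).

## Association and meta-analysis

Variant QC applies MAF, call-rate, imputation-info and Hardy–Weinberg
filters; HWE uses the exact conditional enumeration test on hard genotype
counts (no mid-p). Association is ordinary least squares of each adjusted
phenotype on effect-allele dosage plus covariates with a two-sided t test.
When no dosages are missing the scan is vectorized across variants by
Frisch–Waugh–Lovell residualization, which is algebraically identical to
the per-variant regression (verified against normal-equation oracles to
1e-10); with missingness it falls back to per-variant complete-case fits.
The genomic inflation factor is median(χ²)/0.4549 per phenotype. Twin
relatedness is handled by excluding one member of each monozygotic pair
rather than by a mixed model. Cohorts are combined by fixed-effect
inverse-variance weighting after allele harmonization (betas and EAF
flipped when effect/other alleles are swapped; strand-ambiguous
mismatches dropped); heterogeneity is Cochran's Q on k−1 df. Variants
reported by only a subset of cohorts are pooled over the reporting cohorts
with the count recorded.

## Multiplicity and power

With 78 strongly correlated traits a per-trait Bonferroni correction is
over-conservative. The effective trait count M_eff summarizes the
eigenvalue spectrum of the trait correlation matrix; both the Li–Ji
estimator (sum of I(λ≥1) + frac(λ), the default) and Nyholt's
1 + (M−1)(1 − var(λ)/M) are provided, with the integer floor used for
thresholding. Pairwise-complete correlation matrices can be mildly
indefinite, so eigenvalues above −0.05 are clipped to zero rather than
rejected. Analytic power of the 1-df additive test uses the noncentrality
n·R²/(1−R²) (the simpler n·R² differs by <1% at the effect sizes of
interest and is available via `ncp_form="simple"`), with the two-tailed
normal form Φ(√ncp − z₁₋α/₂) + Φ(−√ncp − z₁₋α/₂); the exact noncentral-χ²
reference agrees to ~4 decimals and is available via `reference="ncx2"`.

## Combined test of dependent tests

Replication evidence over correlated phenotypes uses Fisher's statistic
T = Σ −2 log Pᵢ referred to a scaled χ²: E = 2k,
V = 4k + 2 Σ_{i<j} cov(−2 log Pᵢ, −2 log Pⱼ), scale c = V/2E, df
f = 2E²/V. The pairwise covariance is the cubic polynomial
3.263r + 0.71r² + 0.027r³ in the test-statistic correlation r. The
polynomial is exact for the one-sided upper-tail setting: `cov_exact`
recomputes the covariance by Gauss–Hermite quadrature over a bivariate
standard normal and the maximum deviation over the validated open
interval −0.98 < r < 0.98 (step-0.02 grid) is 1.95×10⁻⁴; at r = ±0.98
exactly the deviation grows to ~2.3×10⁻⁴, which is why the validated
range is open. Calibration checks therefore simulate the null in the
one-sided setting, where empirical type-I error at 0.05 is within
Monte-Carlo error for exchangeable correlations up to 0.9. Applied to
two-sided association p-values with signed phenotype correlations — the
usual practice this method supports — the combination is mildly
conservative at strong positive dependence, a known property of the
approximation rather than of this implementation. Two-stage replication
combines phenotypes within each cohort using that cohort's phenotype
correlation matrix, then combines cohorts as independent (distinct
samples). The pipeline combines over the phenotypes associated with a
locus in discovery (exact replication), not over all 78, which would
dilute single-phenotype signals.

## Polygenic scores

Candidates are tested conditional on the lead SNPs (leads as covariates)
and kept when Bonferroni-adjusted p < 0.05, with the family defaulting to
candidates × phenotypes (per-phenotype correction is a flag); candidates
with conditional R² > 0.99 on the leads are dropped as collinear. Forward
stepwise regression adds, per phenotype, the variant maximizing model R²
until the best addition is not nominally significant (p ≥ 0.05, ties
broken by variant id); ΔR² is the R² increment at entry and final betas
come from the joint model. Scores are PS = Σ βᵢAᵢ with mean-imputation of
missing dosages (count reported); standardization is over the scored
sample (pooled by default, per-group as a flag), and group differences are
tested by one-way ANOVA.

## Selection scans

FST is the Weir–Cockerham (1984) variance-components estimator computed
from per-population sample sizes, allele frequencies, and observed
heterozygote proportions; variants monomorphic in all populations are
excluded and the empirical cutoff is the 99th percentile over scanned
variants. EHH is the probability that two haplotypes from an allele class
are identical at every variant from the core out to a position; iHS
integrates the EHH decay (trapezoid, physical distance in bp — no genetic
map is assumed) separately on derived and ancestral backgrounds until EHH
falls below 0.05 (linear interpolation to the crossing), both directions
summed, and takes ln(iHH_A/iHH_D), standardized within 0.05-wide
derived-frequency bins. Declared edge rules: a gap of more than 200 kb
between consecutive variants truncates the integral; a variant whose EHH
never reaches the cutoff before the region edge is flagged edge-truncated
and excluded from standardization. A focal scan can be standardized and
judged against a reference scan's bin statistics and top-1% cutoff — the
analogue of judging a candidate region against a genome-wide empirical
null, which matters at simulation scale because a sweep's footprint can
occupy more than 1% of a small region and contaminate its own cutoff.

## Heritability

Twin heritability is Falconer's h² = 2(r_MZ − r_DZ) with double-entry
Pearson correlations over pairs (symmetric in co-twin order), pair-dropped
missingness, a pair bootstrap CI, and the raw estimate reported alongside a
[0,1]-clamped display value. The SNP-based estimator is Haseman–Elston
regression of standardized-phenotype cross-products on GRM off-diagonals
(GRM = ZZᵀ/M of standardized dosages; related samples prunable to
off-diagonals < 0.05), with delete-one-block jackknife standard errors.
It is a method-of-moments stand-in for restricted maximum likelihood:
comparisons with twin estimates are qualitative (the expected pattern is
twin estimates exceeding SNP-based ones), and under dense LD with
directionally aligned causal effects the realized genetic variance — the
quantity HE estimates — differs from the nominal sum of per-SNP variance
fractions.

## Synthetic data generator

The generator exists so every stage has inputs with the structure it
assumes. Haplotypes are mosaics of a founder pool (default 100 founder
haplotypes; derived-allele frequencies uniform on [0.05, 0.95]); switch
points form a Poisson process (default 3×10⁻⁶/bp, i.e. ~333 kb segments)
so nearby variants show LD and EHH decays over tens of kb. Populations
share base frequencies shifted by ±af_shift per variant. A partial sweep
forces a carrier fraction of haplotypes to copy the favored founder
outward from the core for exponential-length segments (mean 250–300 kb;
infinite segments reproduce the degenerate all-identical case), with
the derived core allele given exactly to carriers.

Landmark phenotypes start from a bilaterally symmetric 13-landmark
template face (mm units). A causal variant moves the two endpoint
landmarks of its target distance symmetrically along their connecting
axis, so the distance changes by β per dosage unit with
β = ±sqrt(|vf|·2σ²/2p(1−p)) chosen to explain the requested fraction of
the baseline distance variance 2σ² (σ = 1 mm landmark placement noise by
default; the sign of vf sets the direction). Sex and age effects use the
same displacement mechanism, with default amplitudes calibrated so their
joint R² reaches ~21% on the most affected distance. Landmark noise is
decomposed A/C/E by `twin_h2`/`twin_c2`: monozygotic co-twins share the
additive field, dizygotic co-twins correlate 0.5, common environment is
shared within pairs — so every distance inherits r_MZ = h²+c² and
r_DZ = h²/2+c² exactly. Finally each configuration receives a uniform
random rotation, a translation, and a log-uniform scale on [0.8, 1.25],
exercising every degree of freedom GPA claims to remove.

What the generator does not emulate: coalescent genealogies and
recombination maps (mosaic LD is short-ranged and homogeneous), genotyping
or imputation error (dosages are exact), non-Gaussian landmark placement
error, phenotypic covariance beyond what shared landmarks induce, and
assortative or structured mating. Passing tests therefore demonstrate the
estimators' correctness and calibration under a clean generative model,
not robustness to every artifact of real cohort data.

## Problem sizes

The default end-to-end study uses two 2000-sample discovery cohorts, a
2000-sample replication cohort, 120 twin pairs, and a 300-sample diverged
comparison population typed at 400 variants over 2 Mb — sizes at which a
1%-variance variant has ~80% discovery power at 5×10⁻⁸ and replication
power near 1 at the locus-count Bonferroni level, so the pipeline's
behaviour on planted effects is informative. Simulation-backed tests use
cohorts of 600–2000 samples and panels up to 4500 variants; Monte-Carlo
calibration tests use 10,000 replicates (±2 binomial SE acceptance), and
sweep detection uses 50 replicates against per-replicate neutral
reference panels.

## Known limitations

- The combined test inherits the covariance approximation's mild
  conservatism for two-sided p-values at strong positive correlation.
- iHS integrates over physical distance; results are not comparable to
  map-based implementations where recombination rate varies.
- The HE estimator is not REML; its standard errors come from a block
  jackknife and degrade below ~30 samples.
- Greedy distance-based clumping (1 Mb default window) is a stand-in for
  LD-aware clumping; it can merge distinct signals in strong LD regions
  and split one signal spanning more than the window.
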