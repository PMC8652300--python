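# Methods

This note documents the models and procedures implemented in `bdnfnet`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Expression-weighted polygenic score (ePRS)

The score proxies the predicted expression of a gene network anchored on
BDNF in the prefrontal cortex (PFC). Construction:

1. **Co-expression filter.** Mouse genes with |r| ≥ 0.5 against Bdnf in PFC
   are retained (boundary inclusive), each carrying sign(r). The package
   ships a 46-gene snapshot of this table (`bdnfnet/data/`); note one entry
   whose printed symbol is the literal string `NA` (an alias of MARCKS),
   which the readers preserve verbatim.
2. **Homolog mapping.** Mouse → human symbols via an explicit map; unmapped
   genes are dropped and reported, one-to-many homologs are all retained and
   flagged (a SNP can still contribute only once, see assignment below).
   Matching is case-sensitive with no fuzzy fallback.
3. **Developmental enrichment.** A gene is kept when its mean expression
   over the early stages (prenatal through early childhood; configurable
   stage set, default = every non-adult stage) is ≥ 1.5-fold its adult
   expression. The aggregation over early stages is the arithmetic mean —
   the source protocol does not fix one, and the mean is the least surprising
   choice. Adult expression of exactly 0 retains the gene with an
   "infinite fold" flag rather than dividing by zero.
4. **Intervals.** Gene body ± 500 bp flank, 1-based inclusive coordinates,
   clipped at position 1.
5. **SNP assignment.** A SNP joins the score iff its position falls inside a
   flanked interval. A SNP inside several overlapping intervals is attached
   to the gene with the smallest eQTL association p-value among its
   reference rows, so every SNP appears exactly once.
6. **LD clumping.** Greedy: rank by association p ascending (ties broken by
   position, then id, for row-order invariance), take the best remaining SNP
   as index, discard remaining SNPs on the same chromosome within ±500 kb
   whose dosage r² with the index exceeds 0.2. r² is the squared Pearson
   correlation of dosage vectors over samples with both calls present
   (genotype-based, the standard clumping statistic; haplotype phase is not
   needed). The clumping p-values are the eQTL association p-values packaged
   in the weight table; this is configurable since other association scans
   could be substituted.
7. **Scoring.** score(sample) = Σ dosage × eQTL slope × sign(co-expression).
   Missing dosages are mean-imputed as 2 × effect-allele frequency
   (drop-and-rescale is available behind a flag). Alleles are harmonized
   against the weight table: an effect/other swap flips dosage to 2 − d and
   is logged; any other allele mismatch is an error, never a silent drop.

**Genotype QC** precedes everything: samples with call rate < 90%, then SNPs
with call rate < 95%, then MAF < 5% (exactly 5% is kept), then HWE exact
p < 1e-40. The order is not dictated by the QC thresholds themselves; the
sample→SNP→MAF→HWE order mirrors common PLINK practice and is logged with
per-filter counts. The HWE test is the classical two-sided exact test
(conditional on allele counts, summing probabilities of heterozygote counts
no more probable than observed), computed with the stable probability
recurrence; no mid-p correction.

**Stratification PCA.** Variants with MAF > 0.05 are pruned in a sliding
window (50 kb, 5-SNP increment, r² ≥ 0.20 removes the later SNP of a pair),
dosages are centered by 2p̂ and scaled by √(2p̂(1−p̂)) (missing → 0 after
centering), and the top 3 principal components are returned.

## Cumulative prenatal adversity

Ten indicators, one point each, summed (range 0–10): money hassles > 9,
depression (CES-D) > 22, pregnancy anxiety (STAI) > 1.95, abuse present,
marital strain < 2.9, any pregnancy health condition, smoking, gestational
age ≤ 37 weeks, birth percentile < 10 or > 90, income < $30,000/yr. The
strict/inclusive boundaries follow the rubric's wording exactly and are
unit-tested. Two open points were resolved as follows:

- The source prose also mentions an 85th-percentile screening convention for
  the psychometric scales while the rubric prints absolute cut-offs; the
  absolute cut-offs are the default and a within-cohort percentile mode
  (85th; 15th for marital strain, where low is worse) sits behind a flag.
- Missing fields contribute 0 points (no proration) and are counted in
  `n_missing` so sparse records can be excluded downstream; a record with
  every field missing is an error.

Group split for the fusion contrast: at or below the median → low, above →
high. On 47 distinct scores this yields the 24/23 low/high partition; with
heavily tied integer totals the groups can be uneven, which the split report
surfaces.

## Rasch concurrent vertical scaling

Different visit ages receive different item forms; adjacent forms share
common items, and a single joint (concurrent) calibration of the 1PL model
P(correct) = logistic(θ − b) puts all visits on one logit scale. Estimation
is joint maximum likelihood — alternating damped-Newton solves of the score
equations for θ and b — identified by centering b at 0 each sweep;
convergence when the largest parameter change drops below `tol` (default
1e-4). JML is used because it matches the behaviour of the standard
commercial calibration tool for this design; marginal ML is a known
alternative but is not required at these test lengths, and JML's small-k
bias (~k/(k−1)) is negligible at 40-item forms relative to the 0.25-logit
recovery tolerance. Extreme (all-0/all-1) person or item scores are pulled
in by 0.3 score points (configurable) so every estimate is finite, and are
flagged. An unlinked form graph (no common-item path between two forms) is
an error.

Separation statistics: RMSE² = mean(SE²), true variance = var(θ̂) − RMSE²
floored at 0, separation G = true SD / RMSE, reliability = G²/(1+G²) =
true/observed variance; the identity is exact by construction. Reporting
scale: scaled = slope·θ + intercept with slope > 0; the transform constants
are user-set (the cohort's constants are not public), and the synthetic
pipeline uses the affine map that inverts its own ability generation.

## Moderated growth model

Outcome: vertically scaled cognition at ages 6–36 months. Fixed effects (in
canonical order): intercept, ePRS, adversity, ePRS×adversity, age, ePRS×age,
adversity×age, ePRS×adversity×age, age², sex, PC1–3. ePRS and adversity
enter standardized (implied by the ±1 SD trajectory plots); age stays in raw
months (centering is a flag affecting only the intercept's meaning).

Random structure: "participants' age and the quadratic age term" are
interpreted as correlated per-child random slopes on age and age², combined
with AR(1) correlation of the within-child residuals over the ordered
visits. Estimation is maximum likelihood (not REML) so nested-model
pseudo-R² comparisons are coherent: the covariance parameters
(log τ_age, log τ_age², atanh ρ, atanh φ, log σ) are optimized by
Nelder-Mead with the fixed effects profiled out by GLS; children are
grouped by visit-age pattern so each pattern's 4×4 marginal covariance is
assembled once per likelihood evaluation (a cohort-scale fit takes ~0.3 s).
A numerically singular random-effects fit triggers an automatic refit with
the simplified (age-only) structure, flagged in the result. Wald p-values
use a t reference with residual degrees of freedom (n_obs − p) — a
large-sample approximation chosen over Satterthwaite machinery because the
package's claims never rest on the p-values of a single cohort fit.

Effect sizes: marginal pseudo-R² = var(Xβ̂) / (var(Xβ̂) + mean(z'Ψz) + σ²),
conditional adds the random-effect variance to the numerator; Cohen's
f² = (R²_full − R²_reduced)/(1 − R²_full) per dropped term, with < 0.02
small and > 0.15 large. Predicted trajectories are evaluated on the 2×2
grid of ±1 SD ePRS × adversity with covariates at reference values.

## Parallel ICA fusion

Two subject-aligned modalities (SNP weighted-genotype values; in-mask
gray-matter voxels). Model order per modality by minimum description length
on the subject-covariance eigenvalues (the classical criterion:
−N(p−k)·log(geometric/arithmetic mean of trailing eigenvalues) +
½k(2p−k)·log N with N = number of features), floored at 1 with a
"no structure" warning and capped at numerical rank.

Each modality is PCA-whitened to its order and unmixed by infomax ICA
(natural-gradient ascent, logistic nonlinearity, shuffled feature batches;
learning rate 0.015/ln(k+2), annealed by 0.95 when consecutive weight
updates turn by more than 60°; max 512 epochs, tolerance 1e-6 on the weight
change). After each epoch the single most-correlated pair of loading
columns across modalities takes a gradient step up the squared correlation,
applied to the unmixing inverses so sources stay consistent; the constraint
weight λ (default 1) anneals by halving whenever a modality's entropy
objective decreases. This single-pair variant follows the published
algorithm family where the exact toolbox schedule is not specified; λ = 0
reproduces two independent infomax runs *bitwise* (the per-modality random
streams depend only on seed and data shape), which the tests assert.
Components are ordered by explained variance with the sign convention that
the largest-|weight| feature is positive. Feature selection converts each
component's weights to z-scores and keeps |z| > 2.5 (strict). Loading-pair
correlations get two-sided p-values from t = r√((n−2)/(1−r²)); group
contrasts of loadings use the pooled-variance Student's t (df = n₁+n₂−2),
with Welch's variant behind a flag since the published group p-values are
not all consistent with a pooled df-45 test under simple rounding.

## Synthetic data

Every generator is a pure function of (spec, seed) and returns its ground
truth alongside the data; recovery tests read truth only from that object.
Defaults encode the study design: 157 children at 6/12/18/36 months, 47
imaging subjects.

- **Genotypes:** haplotypes from a latent AR(1) Gaussian per LD block
  (default block 10, ρ 0.85) dichotomized at allele-frequency quantiles
  (MAF 0.05–0.5), summed to diploid dosages — dosage r² decays with index
  distance as real LD does, without emulating any real LD map.
- **Reference tables:** 60 genes of which exactly 46 pass the |r| ≥ 0.5
  co-expression cut and 46 the 1.5-fold enrichment cut (mirroring the
  published network's size); eQTL slopes N(0, 0.3); association p-values
  uniform with a spiked low-p subset; 4 SNPs per gene placed inside the
  flanked interval plus 60 decoy SNPs outside every interval.
- **Item responses:** Bernoulli Rasch draws over per-visit forms that share
  common items between adjacent forms; difficulties rise with form so the
  vertical scale is genuinely stretched. Real item content is not emulated.
- **Cohort outcomes:** the published fixed-effect column is the generating
  β. The unpublished variance components default to random age-slope SD
  0.5 points/month, age²-slope SD 0.012, slope correlation −0.2, AR(1)
  φ = 0.3, residual SD 8 points — chosen once so that the fixed-effect
  standard errors of a cohort-scale fit land within about 3× of the
  published ones; they are assumptions, not estimates. The 47-child imaging
  subsample's continuous adversity latent median-splits 23 high / 24 low.
- **Adversity records:** independent Bernoulli indicators whose prevalences
  imply a mean total ≈ 1.3 (the cohort's published mean, used as a
  calibration sanity check only); raw field values are then placed on the
  correct side of each rubric threshold.
- **Fusion data:** sparse spike sources, Gaussian loadings with the linked
  pair planted at *exactly* the requested sample correlation (the noise
  component is residualized against the linked column first — at n = 47–60
  the sampling error of a population-level plant would otherwise dominate
  the ±0.1 recovery band), noise scaled to the requested SNR (default 5).

What passing tests show — and do not show. Recovery at these settings
demonstrates the estimators are correctly implemented and unbiased under
the generating model; it says nothing about robustness to real-data
features the generators omit (genotyping batch effects, non-AR(1) LD,
item misfit and DIF, informative missingness, scanner site effects).

## Problem sizes

The default test-and-reproduction sizes are the study's own (157×4 cohort;
200 replicates for the recovery experiment; 300×40 Rasch recovery; 60
subjects for fusion recovery; 50 replicates for MDL rank recovery), which
keep the full suite and the reproduction script each within a few minutes
on one CPU.

## Known limitations

- JML ability estimates are biased outward for short forms; the package
  reports SEs from the observed information, which understate error for
  extreme-score persons.
- The growth model's p-values use a residual-df t approximation rather than
  Satterthwaite; for small cohorts the interaction p-values are mildly
  anti-conservative.
- The pICA constraint operates on the single best pair per epoch; weak
  secondary linked pairs are enhanced only after the first pair stabilizes.
- `estimate_order_mdl` assumes features ≫ subjects; with few features the
  penalty term is miscalibrated.
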