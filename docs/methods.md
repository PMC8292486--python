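# Methods

## The model

Group-housed pigs affect each other's performance: a pen mate's genotype can
change *my* feed intake. The package fits the classical social (indirect)
genetic effects model to records of pigs housed in pens,

    y = X b + Z_D a_D + Z_S a_S + W l + V g + e

where `a_D` are direct genetic effects (DGE: the effect of an animal's own
genotype on its own phenotype) and `a_S` are social genetic effects (SGE: the
effect its genotype exerts on each pen mate). `Z_D` maps records to the
animal's own effect; row *i* of `Z_S` carries a 1 in the column of every pen
mate of *i* (entries unweighted, no dilution by pen size), so row sums equal
pen size − 1. `l` and `g` are i.i.d. litter and pen-environment effects, `b`
holds sex, test year-month and birth year-month levels.

The genetic effects are jointly Gaussian,

    Var([a_D; a_S]) = C ⊗ K,   C = [[σ²_D, σ_DS], [σ_DS, σ²_S]],

with `K` a relationship matrix. By default `K` is genomic, built from the
centred cross-product GRM

    G = (1/p) Σ_i (X_i − 1 x̄_i)(X_i − 1 x̄_i)ᵀ ,

and the direct–social covariance σ_DS is estimated (a flag fixes it at 0).
A pedigree numerator matrix can be supplied in place of the GRM.

### Scaling of K

The centred GRM above has mean diagonal ≈ 2·mean(pq) (≈ 0.33 for a MAF
spectrum uniform on [0.05, 0.5]), not 1. Variance components estimated
against the raw matrix would therefore be on a marker-heterozygosity scale.
`SocialGeneticModel` rescales `K` to mean diagonal 1 (`normalize_K=True`),
so σ²_D and σ²_S are per-individual variances on the phenotypic scale and
are directly comparable with the simulator's generative values. The GWAS
layer keeps the raw GRM: single-marker p-values are invariant to its scale.

## REML

Variance components are estimated by average-information REML on the dense
covariance V(θ) = Σ_k θ_k A_k. Safeguards:

* a proposed AI step is projected into the parameter space (variance floor
  10⁻¹⁰ × phenotypic variance; C kept positive semidefinite) and backtracked
  by step halving until the restricted log-likelihood does not decrease;
* if no AI direction is admissible an EM-style step (θ² scaled gradient) is
  tried; accepted iterations therefore have non-decreasing log-likelihood;
* a variance pinned at its floor with a downhill gradient leaves the update
  (active set); when σ²_S is floored, σ_DS is frozen at 0, since the PSD
  bound pinches it to nothing and it otherwise oscillates indefinitely;
* `K` is bent to PSD (eigenvalues clipped at 10⁻⁸ × mean diagonal, count
  reported) before use.

Convergence is declared when the largest relative parameter change drops
below 10⁻⁸ (default; 200 iterations maximum) or when the log-likelihood
gains less than 10⁻⁶ for five consecutive iterations with only immaterial
parameter movement — the residual drift in that regime is a crawl along the
PSD boundary of C, not progress toward a different optimum. EBVs and prediction-error variances (PEV) come from the mixed-model
equations at the optimum; the PEV is the corresponding diagonal of the
inverse coefficient matrix.

Accuracy and deregression follow the standard pseudo-phenotype construction:
r = √(1 − PEV/σ²) with the *effect-specific* genetic variance (σ²_D for DGE,
σ²_S for SGE) in the denominator, clamped to 0 when PEV ≥ σ²; the
deregressed EBV is g/r², marked unusable when r² < 0.01 (configurable
floor). Deregression removes shrinkage so the quantity can serve as a GWAS
response.

### Identifiability notes

The pen-environment variance σ²_g and the social variance σ²_S both generate
pen-level covariance: the summed pen-mate SGE differs from a pen effect only
through within-pen leave-one-out contrasts and between-pen genomic
covariance. At desk scale (pens of 10, n of a few hundred) the two are
weakly separated; σ̂²_g frequently lands on the zero boundary while σ̂²_S is
recovered well in the median across replicates. This is a property of the
design, not of the optimizer, and is why the recovery checks assert medians
over seeded replicates rather than single fits.

## Mixed-model GWAS

Each deregressed EBV vector (per trait × effect) is the response of the
single-marker mixed model y = Xm + a + e, a ~ N(0, G σ²_a), e ~ N(0, I σ²_e)
— the standard "unified" MLM. The null model is fitted spectrally: with
G = U D Uᵀ the data rotate to independent coordinates with variances
proportional to d_i + δ, δ = σ²_e/σ²_a, and δ is found by a bounded scalar
search on log δ ∈ [−10, 10]. Negative GRM eigenvalues (the centred GRM is
rank-deficient by construction) are clipped at zero and counted.

Markers are tested by GLS under the null covariance, either re-using the
null δ for every marker (P3D, default) or re-optimising δ per marker
(`mode="per-marker-reml"`). The Wald statistic (m̂/SE)² is referred to
F(1, n − q) by default, which reduces *exactly* to the ordinary-regression
t-test when σ²_a = 0; a χ²₁ reference is available (`reference="chisq"`).
Monomorphic and covariate-collinear markers are reported with a missing p
and a reason code. Haplotype alleles are tested through the same machinery
as biallelic pseudo-markers.

Thresholds are Bonferroni: genome-wide 0.05/N, suggestive 1/N, with N the
number of tests in the scan (SNPs, or retained haplotype alleles); displayed
at 3 significant digits. The genomic inflation factor λ uses the median
method — median of the observed χ²₁ quantiles divided by 0.4549 — with a
GenABEL-style regression estimator behind `method="regression"`.

## Haplotype blocks and alleles

Blocks follow the Gabriel confidence-interval method as parameterised in
PLINK (`--blocks`): for every marker pair within 1 Mb a likelihood-profile
90% confidence interval on |D′| is computed (haplotype counts taken directly
from phase when available, otherwise via two-locus EM; the profile fixes the
allele frequencies and scans D′ on a 0.001 grid). A pair is *strong LD* when
CI_low ≥ 0.8 and CI_high ≥ 0.98, *strong recombination* when CI_high < 0.90,
otherwise uninformative. A span of two or more SNPs becomes a candidate
block when ≥ 95% of its informative pairs are strong; overlapping candidates
are resolved longest-span-first (ties: more SNPs, then leftmost), giving a
deterministic non-overlapping tiling. Markers with > 10% missingness are
excluded from block building.

Each block's distinct haplotype strings over its member SNPs are the alleles
of one multi-allelic locus; the dosage of allele k for an individual is the
number of its two haplotypes equal to k (rows of the unfiltered dosage
matrix sum to 2). Alleles at frequency ≤ 0.01 are dropped from testing but
kept in the frequency table. Phase must come from the input (imputation
pipelines emit phased genotypes); no phasing algorithm is implemented.

## QC and reporting conventions

Marker QC applies, in a fixed order that makes the report deterministic:
no-position/sex-chromosome removal, optional quality-score filter (e.g.
imputation R² < 0.8), call rate < 0.90, MAF < 0.05, exact Hardy-Weinberg
test p < 10⁻⁶ (Wigginton-style exact test, as genotype-QC tools use). All
removals are strict inequalities; a marker is counted once, under the first
filter that rejects it.

Significant hits are tiered by strict comparison against the thresholds
(p exactly equal to a threshold is not significant). QTL regions are 1-Mb
windows centred on each significant marker, displayed in Mb rounded half-up
to 2 decimals; windows near a chromosome start are clamped to a lower bound
of 1 bp with the width preserved. DGE/SGE hit overlap is an exact set
partition keyed by (chromosome, bp) — coordinates rather than ids, because
ids differ across marker panels.

## The synthetic cohort

The generator emulates a grower-finisher performance test. Phased genotypes
are LD-blocked: each block carries a founder pool (default 8 haplotypes,
per-SNP allele frequency uniform on [maf_min, 0.5]) from which every
individual copies two, with Dirichlet-weighted founder probabilities so some
haplotypes are rare; copying induces within-block LD and family-like genomic
relatedness, while between-block gaps (2 Mb) guarantee block separation.
Positions increase strictly within chromosome (1 kb spacing inside blocks).

True breeding values are a polygenic draw G^{1/2}z (computed from the thin
SVD of the centred dosage matrix) with the configured direct-social
correlation, plus sparse QTL effects; each total is rescaled so its realized
variance equals σ²_D (resp. σ²_S) exactly, which keeps recovery checks
sharp. Phenotypes follow the generative model above with small fixed-effect
level shifts (sex ±0.1, a few year-month levels ≤ 0.08) that exercise X
without dominating the variance. Pens are contiguous chunks of a random
permutation (the last pen may be smaller and is kept); litters are an
independent random partition, so litter and pen are crossed.

Default variance components partition a unit phenotypic variance: σ²_D =
0.30, σ²_S = 0.03, σ_DS = 0, σ²_litter = σ²_group = 0.05, σ²_e = 0.57. These
are plausible values for socially affected production traits, chosen once;
they are not estimates from any real dataset. The commercial pen size is 20;
the desk-scale default is 10 with n = 600 and 3,000 SNPs, sizes at which
every stage runs in seconds to minutes on one CPU.

Feeder records are one visit per feed day with a linear body-weight
trajectory plus N(0, 0.4 kg) measurement noise; per-visit feed and
occupation times are random splits that sum exactly to the pig's total feed
intake and feeder time, so ADFI and TPD re-derived from the records match
the generator's targets to numerical precision, and the ADG regression is
always defined (≥ 2 visits).

What the generator does *not* emulate: genotyping error, pedigree structure
across generations, selection, non-random pen assignment, seasonal trends,
or missing-data patterns of real feeder systems. Passing tests therefore
demonstrate correctness of the estimation and testing machinery under the
stated generative model, not robustness to real-data pathologies.

## Trait derivations

From raw records: ADG is the OLS slope of all visit body weights on test day
(not an endpoint difference); ADFI = TFI/feed days; TPD = total feeder
time/feed days; FS = ADFI × 1000/TPD (kg→g conversion, since ADFI is in kg/d
and FS in g/min). FCR = TFI/(W₂ − W₁). D100 and B100 standardise tested days
and backfat to 100 kg using sex-specific constants (A = 50.775 males /
46.415 females; B = −7.277 / −9.440); both are exact fixed points at
W₂ = 100. AMW = (W₂^1.6 − W₁^1.6)/(1.6 (W₂ − W₁)), with the analytic limit
W₁^0.6 at W₂ = W₁ (continuity rather than NaN). RFI = ADFI − 14.1 ADG −
2.83 BFT − 110.9 AMW is evaluated literally; the regression coefficients
carry no published unit convention (with kg/d inputs the result cannot be on
a grams scale), so a `convention` switch offers both the literal kg evaluation
and a g/d variant, and neither is asserted as canonical.

## Validation-study conventions

* Recovery studies use 20 seeded replicates at n = 600, pens of 10, 1,200
  markers, and compare medians: σ̂²_D within 25% of 0.30 and σ̂²_S within two
  empirical standard errors of 0.03; with σ²_S = 0 the median σ̂²_S must stay
  below 5% of the phenotypic variance.
* MLM calibration uses 2,000 null markers at n = 400 with a 50/50 polygenic/
  residual response; the empirical rejection rate at α = 0.05 must sit in the
  exact binomial 95% interval, and λ on a uniform p-grid must equal 1.00 ±
  0.01.
* Power floors plant (a) a SNP explaining 5% of the response variance and
  (b) a haplotype allele of frequency ≈ 0.05 with an effect of 0.5 phenotypic
  SD per standard deviation of allele dosage, at n = 600 with a 30%-polygenic
  background, requiring detection at the scan's suggestive threshold in ≥ 80%
  of 20 replicates. The per-dosage-SD effect convention is the package's
  design choice: it is the convention of standard GWAS power calculations,
  and a per-allele-copy reading of the same number yields a non-centrality
  (~14) whose theoretical power at these thresholds is ~0.5, i.e. not a
  usable floor.
* The problem sizes above were chosen so the full validation battery runs in
  a few minutes on a single CPU; they are desk-scale stand-ins, not the
  dimensions of any real dataset.

## Known limitations

* Single-trait REML only; no multi-trait or maternal-effect extensions.
* Dense O(n³) linear algebra throughout the social model: comfortable to a
  few thousand records, not for national evaluations.
* The haplotype scan treats each allele marginally; no omnibus per-locus
  test is provided.
* Sample-level QC (relatedness pruning, heterozygosity outliers) and
  genotype imputation are out of scope; an imputation quality score is only
  consumed as a marker filter.
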