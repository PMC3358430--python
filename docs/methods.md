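# Methods

`crossqtl` implements a cross-tissue cis-eQTL mapping pipeline of the kind
used in GWAS-era blood/brain expression studies, together with a synthetic
cohort generator that makes the whole chain testable without any external
data. This note records the statistical model, the defaults and why they
were chosen, what the simulator does and does not emulate, and the design
decisions made where more than one reasonable choice existed.

## The association model

For each SNP:probe pair within a ±500 kb cis window, expression is
regressed on allelic dosage by ordinary least squares:

    y_i = mu + beta * d_i + gamma' c_i + e_i

where `d_i` in [0, 2] is the expected minor-allele count (imputed dosage
used as-is, not rounded), and `c_i` collects the covariates: age at death,
gender, the first two MDS components (C1, C2), post-mortem interval, tissue
bank, and hybridization batch. Categorical covariates are expanded to
indicators against the most frequent level. The dose coefficient's
two-sided p-value uses the t distribution with `n - k` degrees of freedom.
Samples with any missing value in the model are dropped pairwise per fit.
SNPs with fewer than 3 minor-allele homozygotes — counted on rounded
(hard-call) genotypes — are excluded before fitting, because the regression
is otherwise driven by a handful of extreme dosage values.

Multiple testing is controlled per tissue and per analysis track with
Benjamini–Hochberg at 5% FDR. Two tracks exist: the *consensus* track
(pairs testable in every tissue, adjusted within the consensus family) and
the *expression-restricted* track (pairs testable only where the probe
passes detection). Adjusting the tracks separately keeps the two analyses'
FDR guarantees independent.

The probe's genomic reference point for cis pairing is the midpoint of its
50-mer interval (always a half-integer for BED-style 0-based half-open
coordinates); the 500 kb window is inclusive at its edge. Chromosome name
dialects ("chr1" vs "1") are normalized before pairing.

## Quality control

SNP-level: drop if call rate < 0.95, MAF < 0.01, or HWE exact p < 1e-7;
imputed SNPs are instead dropped if MAF < 0.01 or imputation r² < 0.3 (call
rate and HWE are not meaningful for imputed dosages). The HWE test is the
exact conditional test (enumeration of heterozygote counts given allele
counts, plain p, no mid-p), the convention of standard genotype-QC tools.

Sample-level: pairwise IBS distances (1 − mean shared-allele fraction on
hard genotypes) feed classical Torgerson MDS; samples beyond 3 SD from the
reference-set mean on C1 or C2 are ancestry outliers. Relatedness uses the
method-of-moments IBD estimator π̂ = P(IBD=2) + P(IBD=1)/2 from IBS counts,
with falling-factorial finite-sample corrections for in-sample allele
frequencies; only the final π̂ is clamped to [0, 1] (clamping the per-state
estimates first would bias π̂ upward for unrelated pairs). Pairs with
π̂ strictly above 0.15 lose one member (lower call rate; ties drop the
later sample id — one-member removal is a configurable choice, the
alternative of dropping both is not the default). Because the estimator's
sampling noise at few markers swamps the 0.15 threshold, the step is
skipped with a warning below 100 polymorphic SNPs.

LD pruning is greedy within 50-SNP windows advanced by 5 SNPs: the later
member of any pair with dosage r² > 0.2 is removed. Keeping the earlier
(positional) SNP is a simple deterministic tie-break; the variance-based
choice some tools make is not replicated.

## Expression filtering and rank profiles

Probes enter analysis only if detected (detection p < 0.01) in strictly
more than 95% of samples, are flagged `good` (unique mapping, clean
design), and contain no analyzed SNP within the 50-mer (a SNP under the
probe perturbs hybridization and mimics an eQTL). Coordinate conventions
are fixed repo-wide: SNPs are 1-based points, probe intervals 0-based
half-open, so a SNP at position P overlaps [start, end) iff
start < P <= end.

Percentile-rank profiles rank probes by per-probe mean (or variance) of
expression; probes failing detection in a tissue get rank 0 there, and the
denominator is the total probe count, so the top detected probe scores 1.0
and profiles are comparable across tissues with different detected counts.
Ties take average ranks.

## Sharing classification

For consensus pairs, with q-values per tissue at threshold 0.05:
`shared_all` = significant in blood and (strict mode, default) both brain
regions; `blood_specific` = significant in blood only; `brain_specific` =
significant in at least one brain region but not blood; otherwise `null`.
Under strict mode a pair significant in blood and exactly one brain region
is `null`; the relaxed mode (`strict=False`, "any brain region") calls it
`shared_all`. Expression-restricted pairs are classed by which tissue
group could test them. Direction consistency requires all per-tissue betas
to share a strict sign. Proportions are compared with Pearson chi-squared
(no continuity correction) and the pooled two-proportion z-test, which
coincide (chi² = z²) on 2×2 tables.

## Power

Under the additive model with genotype variance v = 2p(1−p), the
non-centrality of the dosage test is λ = Z·√(n·v)/σ_e and the closed-form
power is Φ(λ − z_{α/2}) + Φ(−λ − z_{α/2}). Two variance conventions are
supported: `total_variance_1` standardizes the phenotype (σ_e = √(1 −
Z²v), valid only while Z²v < 1) and `residual_variance_1` leaves σ_e = 1.
Wide effect grids (Z up to 2 across all MAFs) are only representable under
the residual convention.

The significance level behind the two reported cohort powers (98.8% at
n = 501, 93.9% at n = 399, both at MAF 0.2 and Z = 0.5) is not stated, so
`calibrate_alpha` recovers it by one-dimensional root finding on the
critical value jointly against both values. Under `total_variance_1` a
single two-sided α = 1.4002e-5 (z_{α/2} = 4.344) reproduces both to within
2e-5 — a Bonferroni-scale threshold consistent with a genome-scale scan —
whereas the residual convention leaves a residual of ~9e-4 on the n = 501
value. `total_variance_1` with the fitted α is therefore the package
default (`power.default_alpha()`). The fitted pair is a reconstruction,
not a reported fact.

The Φ formula evaluates the non-centrality at the *expected* genotype
variance and uses a normal threshold. The exact finite-sample power of the
OLS t-test differs by up to ~0.015 absolute (low MAF, moderate power, or
very small α): the t critical value, the noncentral-t's inflated spread,
and the sampling variability of the genotype sum of squares all contribute.
`analytic_power(..., exact=True)` computes the exact version: noncentral-t
tail probabilities averaged over the genotype-sum-of-squares distribution
with 41-node Gauss–Hermite quadrature — deterministic, no simulation. The
Monte-Carlo validator (`mc_power`: simulate HWE genotypes, fit OLS, count
rejections) agrees with the exact form within Monte-Carlo error across a
grid of n ∈ {200, 399, 501}, MAF ∈ {0.05, 0.2, 0.4}, Z ∈ {0.1, 0.5, 1.0}
at α = 0.05 with 10,000 replicates; the Φ closed form is kept as the
default because it is the transparent textbook expression and is what the
calibration targets.

## The synthetic cohort generator

`simcohort` emulates the statistical structure the pipeline consumes, not
the raw data:

- **Genotypes**: hard genotypes are Binomial(2, MAF) draws (HWE exactly by
  construction); MAFs uniform on a configurable range. Planted duplicate
  pairs are byte-identical rows; planted ancestry outliers are drawn at
  allele frequencies shifted by a configurable amount (default +0.2).
- **Dosages**: `dosage = r·g + (1−r)·2p + e` with `r = dosage_rsq` and the
  noise SD set so corr²(dosage, genotype) = r, matching imputation-r²
  semantics. The final clip into [0, 2] censors noise tails and raises the
  achieved r² slightly (~0.03 at r² = 0.6). `dosage_rsq = 1` gives exact
  genotypes.
- **Expression**: y = baseline + probe offset + β·dose·[tissue in effect's
  tissue set] + covariate loadings + N(0, σ²), with σ = 1 by default so
  planted β is in residual-SD units. Per-probe baseline offsets (SD 1) are
  derived deterministically from the probe id, so all tissues share one
  expression landscape and rank profiles are comparable. Numeric covariates
  load at 0.1 SD each after standardization, categorical levels get seeded
  offsets of the same scale — enough to make covariate adjustment matter
  without dominating the genetic signal. The real data's noise variance and
  covariate effect sizes are unknown; these defaults are explicit,
  configurable choices.
- **Detection p-values**: uniform below 0.01 where the probe is expressed,
  uniform on (0.02, 1) where it is not — no intensity model; the detection
  filter's planted truth is exact.
- **Catalog**: records satisfy all six inclusion criteria (discovery
  p < 5e-8, initial n > 1000, replication n > 500, > 100,000 SNPs, European
  ancestry, risk-allele frequency ≥ 0.01) or violate a known random subset,
  with truth labels stored alongside.

What the simulator does **not** emulate: LD structure (SNPs are
independent, so pruning tests plant correlation explicitly), haplotypes
and actual imputation, raw array intensities and normalization, missing
genotypes, and realistic expression covariance between probes. Passing
tests therefore demonstrate the correctness of the statistical machinery
under the stated generative model, not robustness to every artifact of
real array data.

## Problem sizes used in the test suite

The replicate-based checks run at reduced but statistically meaningful
scale, chosen once: FDR control uses 200 null cohorts of 200 samples x 500
consensus pairs across three tissues; planted-effect recovery uses 100
cohorts of 501 samples with one β = 0.5 effect (MAF 0.2) among ~150 cis
pairs; Monte-Carlo/analytic concordance uses 10,000 replicates per grid
point. The whole suite completes in a couple of minutes on one CPU.

## Numerical choices and degenerate inputs

- OLS is solved by QR; a relative diagonal tolerance of 1e-10 flags
  collinear designs (including constant dosage) as `status="collinear"`
  rather than raising. At least one residual degree of freedom is required
  (`n ≥ k + 1`); smaller designs return `insufficient_n`.
- HWE enumeration works in log-space with a 1e-12 relative tolerance when
  summing configurations "no more probable than observed", guarding float
  ties against the exact-fraction answer.
- Monomorphic genotype draws in `mc_power` count as non-rejections.
- A zero-margin 2×2 table yields p = 1 with a `degenerate` flag.
- Minor-allele ties at frequency 0.5 resolve to the lexicographically
  smaller allele string; dosage 0.5 rounds up (toward the heterozygote).
- Empty p-value lists produce empty BH output; an all-identical genotype
  matrix yields zero MDS components and no outliers.

## Known limitations

- π̂ retains a small positive bias in very small cohorts even with the
  finite-sample corrections (the pair under test contributes to the
  frequency estimates); borderline flags near 0.15 are possible at ~500
  markers.
- The catalog ancestry match is a case-insensitive substring test on free
  text, the pragmatic choice for an uncontrolled vocabulary.
- `filter_catalog` treats duplicate SNP ids across studies as distinct
  records; `distinct_snp_view` provides per-SNP counting.
- No trans-eQTL scan, permutation FDR, or mixed-model relatedness
  correction: stratification is handled through MDS covariates only.
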