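# Methods

## The problem

A genetic variant reliably associated with both DNA methylation at a CpG
site (a *cis*-meQTL) and a complex trait admits four explanations:
(1) the variant's effect on the trait is **mediated** by methylation;
(2) the meQTL is in **linkage disequilibrium** with a distinct trait-causal
variant; (3) the variant affects the trait, which in turn alters
methylation (**reverse causation**); (4) the variant affects methylation
and trait through **independent pathways** (horizontal pleiotropy).
`methylmr` implements the full analysis chain used to sort candidate loci
among these explanations — cis-meQTL instrument selection, two-sample
Mendelian randomization (MR) in both directions, permutation-based
joint-likelihood colocalization, family-wise multiplicity control, and
matched-background annotation enrichment — together with a synthetic-data
generator that plants each of the four causal structures (plus a null) so
that every stage can be validated against known ground truth.

## Two-sample MR estimators

With methylation M as exposure, trait Y as outcome and variant Z as
instrument, the single-instrument estimate is the Wald ratio

    beta_hat = beta_{Y|Z} / beta_{M|Z}

with the three-term delta-method variance

    se^2 = se_Y^2/beta_M^2 + beta_Y^2 se_M^2/beta_M^4
           - 2 beta_Y cov(beta_M, beta_Y)/beta_M^3 ,

where `cov` is exposed as a parameter but zero in the two-sample setting
(non-overlapping samples). With k >= 2 instruments the fixed-effect IVW
estimate weights outcome effects by their precision:

    beta_hat = sum_k X_k Y_k s_k^-2 / sum_k X_k^2 s_k^-2 ,
    se_hat   = sqrt(1 / sum_k X_k^2 s_k^-2) .

p-values are two-sided standard normal, the summary-data MR convention.
Note that a widely circulated statement of the Wald ratio labels the
numerator as the regression "of the exposure"; this package fixes the
standard convention outcome-over-exposure, which is the only orientation
under which the mediation scenario recovers its planted effect.

Two estimator facts the test suite pins down explicitly:

* a single-instrument IVW has the same point estimate as the Wald ratio
  but a smaller first-order SE (`se_out/|X|`), since it ignores exposure
  uncertainty — the pipeline therefore always dispatches one-instrument
  sets to the Wald ratio;
* the ratio of two normals has no finite variance, so the Monte-Carlo
  check of the delta SE compares against a robust scale (IQR/1.349) of
  10^6 propagated draws; the plain sample SD at a 10-sigma instrument is
  finite in practice but sits ~2% above the delta value through
  second-order curvature. That inflation is a property of the ratio, not
  an implementation error, and is bounded separately in the tests.

## Instrument selection and harmonization

Instruments are cis-meQTL: per-SNP simple regression of methylation on
dosage within 1 Mb of the CpG (two-sided p from t with n-2 df), followed
by greedy LD clumping — eligible SNPs (p < 1e-7) visited by ascending p
(ties broken lexicographically by SNP id so the result is independent of
input order), each kept SNP removing everything with dosage r² >= 0.01
against it. Clumping r² is computed in the same cohort the scan ran in. A
CpG with no eligible SNP is excluded downstream, not an error.

Harmonization aligns outcome records to the exposure's effect allele
(swap → sign flip; strand flip → complement). Palindromic SNPs are
resolved by comparing effect-allele frequencies across the two datasets
and dropped when both frequencies lie in [0.42, 0.58] — a declared
default band, since frequency inference is meaningless near 0.5. When an
instrument is absent from the outcome dataset, the best reference-panel
proxy with r² >= 0.8 substitutes for it; the exposure effect is mapped
onto the proxy through the sign of the panel dosage correlation, and
mutual instrument independence is re-checked after substitution.

## Colocalization

MR cannot tell explanation (2) from the others, because an MR hit only
needs the meQTL to be *correlated* with a trait-causal variant. The
colocalization statistic contrasts single-causal-variant placements.
With per-SNP log-likelihood gains l_t(i) = z_{t,i}^2/2,

    Lambda = max_i [l1(i) + l2(i)]
             - max_{(i,j): r2_ij < 0.8} [l1(i) + l2(j)] ,

i.e. best shared placement minus best *distinguishable* distinct
placement. Pairs in LD at r² >= 0.8 are merged with the shared
hypothesis, honouring the stated resolution limit of joint likelihood
mapping at high LD; the second limit (weak QTLs, p > 0.01) is excluded
upstream by the instrument inclusion rule. This is a reimplementation in
spirit of joint likelihood mapping — the concrete statistic is this
package's formulation, not a bit-compatible port of any released tool.

Significance uses the individual-level trait: the methylation vector is
permuted whole across samples (LD among SNPs preserved; the
genotype–methylation link destroyed), methylation z-scores recomputed
against fixed genotypes, and Lambda recomputed against the fixed trait
summary statistics. p = (1 + #{Lambda_perm >= Lambda_obs})/(n_perm + 1)
(add-one estimator; minimum attainable p is 1/(n_perm+1)). The
permutations reuse standardized genotype cross-products; a test asserts
bit-level agreement with naive re-scanning. The number of permutations is
scaled to the number of associations being followed up (20 per follow-up
test by default, bounded by `min_perm`/`max_perm`), since the family
threshold 0.05/n must be resolvable.

**Calibration.** The permutation test is *exactly* calibrated under
exchangeability (methylation unrelated to local genotype): there the p
distribution is discretely uniform, and a dedicated test verifies this.
Under a *linkage* null — a real, strong meQTL at one variant and the
trait signal at another — permutation destroys the methylation signal, so
the observed Lambda sits far in the left tail of the permutation
distribution and p concentrates near 1. The test is therefore
conservative under linkage (empirical rejection ~0 at alpha 0.05 with
r² = 0.25 between the causal variants), which protects the
shared-variant calls; it is not uniform there, and no scheme that
permutes the raw individual-level data can make it so.

## Multiplicity

Forward-MR discovery uses 0.05 divided by the number of tests; when a
trait correlation matrix is available the denominator can instead be the
Li–Ji effective number of independent tests,
Meff = sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))] over the
eigenvalues of the correlation matrix (eigenvalues are rounded to 10
decimals first: the floor is discontinuous at integers and bare floating
point would count lambda = 2 - 1e-16 as two tests). Trait correlations
can be estimated from MR z-scores across CpGs when phenotypic
correlations are unavailable. One caveat the tests document: Li–Ji is not
monotone under trait duplication — any matrix whose eigenvalues all lie
below 2 yields Meff = M exactly, so adding a duplicated trait can raise
Meff by up to (but never more than) 1. Downstream stages use plain
Bonferroni over their follow-up counts (0.05/1148-style thresholds).

## Enrichment

Hit CpGs are tested for overlap with BED tracks (0-based half-open; a
1-based CpG at position p overlaps [start, end) iff start <= p-1 < end).
Because array CpGs are unevenly distributed over genomic contexts, the
null is matched on annotation class (island/shore/body): the
hypergeometric population is the hit set plus a class-matched background
(10x the hit count by default, largest-remainder allocation), and the
permutation p redraws matched backgrounds of the hit-set size 10 000
times by default. Within a matching class the overlap count of a
without-replacement draw is exactly hypergeometric, so permutation counts
are drawn from that distribution directly; a test verifies
distributional identity with explicit resampling. Proximal, possibly
co-methylated probes are pruned greedily before testing (default 1 kb —
the pruning distance is a package default, as no canonical value exists).

## The synthetic cohort generator

Genotypes: a Gaussian copula. Latent standard normals follow a
first-order autoregressive chain (corr `ld_decay`, default 0.9) and are
thresholded at Phi^-1(MAF) per haplotype; two haplotypes sum to a {0,1,2}
dosage, so the dosage variance is exactly 2f(1-f). At the default decay,
adjacent-SNP dosage r² is ~0.4 — block-like cis LD at 5 kb spacing. For
the linkage scenario the trait-causal SNP's latent variable is mixed with
the meQTL's at a weight solved numerically (bivariate-normal orthant mass
inverted by Brent's method) so the expected dosage r² equals `linkage_r2`
exactly; the two causal SNPs share a MAF so any target below 1 is
feasible, and an infeasible target raises an error rather than silently
missing it.

Methylation sits on a continuous standardized scale (beta_gm per allele,
unit-variance noise) — the scale rank-normalized array data presents to
the estimators. Bounded beta-values, probe artifacts, cell-composition
and batch structure are deliberately not modelled, so passing tests
certify the statistical machinery, not robustness to array-specific
noise.

Trait summary statistics at GWAS scale (n_gwas = 1e5 by default) are
generated analytically: the true marginal effect of every SNP follows
from the generative path coefficients and the expected copula LD
(e.g. mediation gives beta_my·beta_gm·corr(G_j, G_meqtl)·sd_meqtl/sd_j),
and observed effects are drawn around it with se = 1/sqrt(2f(1-f)n_gwas).
This gives two-sample realism without simulating 1e5 individuals, and
the analytic marginals are verified against brute-force regression on
simulated cohorts of 2x10^5.

Scenario defaults are the study conditions of the whole test suite:
n_cohort = 1000 (the scale of a mother–offspring methylation cohort),
40 cis SNPs, MAF uniform on (0.1, 0.5), beta_gm = 0.5, beta_my = 0.4,
beta_gy = 0.3, beta_yg_m = 0.3, linkage_r2 = 0.25. In the
reverse-causation scenario the trait is driven by 5 unlinked instrument
SNPs carried on a separate chromosome (effect beta_gy each) and
methylation gains beta_yg_m·Y; the region meQTL keeps its beta_gm effect
but has no path to the trait, so forward MR is null there while reverse
MR — trait instruments as exposure, the in-cohort methylation scan as
outcome — recovers beta_yg_m. Simulated meQTL effect sizes are free
parameters of the generator, not calibrated to any particular cohort.

Every stochastic call threads an explicit seed; simulation, permutation
and enrichment streams are spawned independently from the run seed, and
identical config + seed reproduces every output file byte-identically.

## Pipeline and problem sizes

The orchestrated run mirrors the discovery design: forward MR over every
instrumented CpG x trait (threshold 0.05/tests) → colocalization of the
survivors (threshold 0.05/survivors) → reverse MR, replication and
expression MR over the shared-variant class. Replication re-simulates
the exposure cohort and redraws the outcome around the same true
marginals (independent samples, same truth) and requires both the
Bonferroni threshold over attempted hits and sign agreement with
discovery. One departure of desk-scale simulation from the large-scale
setting is worth flagging: simulated trait instruments live in the same
cis region as the meQTL, so for mediation hits the reverse MR reuses the
shared variant and is "significant" by construction — the
single-shared-instrument situation in which the direction of effect is
not robustly distinguishable; such rows are flagged SINGLE_INSTRUMENT.

Default validation sizes were chosen so the whole suite runs in minutes
on one core: 200 regions per scenario for power and error-rate studies,
199 permutations for alpha = 0.05 colocalization decisions, 10^6 draws
for the Monte-Carlo delta check. At those sizes the observed operating
characteristics are: forward-MR power ~1.0 for mediation and pleiotropy
at batch-scaled thresholds, coloc detection ~1.0 under mediation versus
rejection ~0 under linkage at r² = 0.25, reverse-MR power ~0.95, null MR
rejection ~0.03–0.05 at alpha 0.05 with uniform p (the slight
conservatism is the exposure-uncertainty term of the Wald SE), and
forward standard errors an order of magnitude smaller than reverse ones
(~0.03 vs ~0.24 at matched configs) — the power asymmetry that motivates
running reverse MR only on discovery hits.

## Known limitations

* Biallelic SNPs only; no INDEL or multi-allelic harmonization.
* Fixed-effect IVW only; no MR-Egger, weighted-median or heterogeneity
  statistics, which require many-instrument exposures that cis-only
  instrument sets rarely provide.
* The colocalization statistic assumes a single causal variant per trait
  per region and cannot separate mediation from pleiotropy — no
  cis-instrument method can.
* The permutation coloc p is conservative (not uniform) under strong
  linkage nulls; see Calibration above.
* The generator's annotation tracks plant marginal overlap enrichment
  only; no spatial autocorrelation of annotations along the genome.
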