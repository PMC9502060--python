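# Methods

`dapes` implements a directional-anchor-gene pharmagenic enrichment score
(PES) framework: genetically predicted expression is used to nominate drug
targets whose risk-increasing direction of expression an approved compound
could reverse, and polygenic scores restricted to each target's interaction
network are then used to find the individuals whose genetic risk is
concentrated near that target. This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Anchor-gene discovery

**TWAS/PWAS.** For a gene model with harmonized expression weights `w` over a
set of variants with GWAS z-scores `z` and LD correlation `V`,

    z_twas = w'z / sqrt(w'Vw),

interpreted as the genetic covariance between imputed expression and the
trait. The LD matrix is conditioned as `V <- 0.95 V + 0.05 I` before the
quadratic form (ridge of 5%); genes whose regularized quadratic form is
non-positive are skipped. Protein weight panels run through the identical
code path. Multiple-testing correction is Bonferroni with the divisor equal
to the number of gene x tissue models tested — deliberately conservative,
since a gene measured in several tissues counts once per tissue.

**Finemapping.** Loci are finemapped over the single-causal-gene
configuration space plus a null configuration. Each gene's approximate Bayes
factor is Wakefield's, `(1+W)^(-1/2) exp(z²W / 2(1+W))` with prior variance
`W = 40` and per-gene prior 1e-3 (defaults); the null configuration receives
`max(1 - m·1e-3, 1e-6)`. The 90% credible set is the smallest
PIP-sorted gene set with cumulative PIP >= 0.9. Because the configuration
space is single-causal, predicted-expression correlation between genes does
not enter the posterior; the full multi-causal enumeration of the wider
finemapping literature is out of scope and this is documented as an
approximation of it. Flags: PIP > 0.8 "high", PIP > 0.4 "moderate".

Frequentist coverage of the credible sets depends on the signal regime: with
strong signals the sets over-cover (a one-gene set with PIP 0.99 contains
the causal gene ~99% of the time), while in a moderate-signal regime
(12-gene loci, causal z-variance ~5 against the default analysis prior) the
sets cover at approximately the nominal 90%. The calibration experiment in
the test suite uses the moderate regime for exactly this reason.

**Colocalization.** Standard five-hypothesis approximate-Bayes-factor
colocalization with priors p1 = p2 = 1e-4, p12 = 1e-5 and per-trait
Wakefield ABFs (prior effect SD 0.2 for the case-control trait, 0.15 for the
quantitative expression trait), accumulated with log-sum-exp.

**Mendelian randomization.** Instruments must be genome-wide significant
(p < 5e-8), hit at most three genes, and survive greedy 1-Mb clumping at
r² < 0.001; trans-QTLs are excluded by default. Effects are per SD of
expression: Wald ratio `beta_gwas / beta_qtl` with first-order delta SE
`|se_gwas / beta_qtl|` for a single instrument, fixed-effect IVW otherwise.
An empty instrument set is a legitimate outcome ("no IV"), not an error.

**Anchor calls.** A Bonferroni-significant TWAS gene becomes a candidate
anchor at tier `high_pip` (PIP > 0.8) or `moderate_pip_coloc` (PIP > 0.4 and
PP_H4 > 0.8). Bonferroni-significant MR hits in the concordant direction
annotate calls or add `mr_supported` genes. Cross-tissue direction conflicts
suppress the call (conservative; majority voting is not attempted). Drugs
match when the interaction class opposes the risk direction
(agonist/activator for protective *increased* expression,
antagonist/inhibitor/blocker for *decreased*) and the interaction is
reported in DrugBank plus at least one other source. Calls without a
matching drug are logged and omitted from the final table.

## Networks and gene-set association

Anchor networks are first neighborhoods under edges with confidence
strictly above 0.7 on the experimental or curated-database channels; the
anchor itself is included or excluded by flag (both modes are used in the
analyses). Edge enrichment compares the induced member-member edge count to
same-size uniform random gene draws (degree-matched draws by flag);
empirical p uses +1 smoothing, making it discrete and conservative at the
resolution of tie mass. Overrepresentation is a one-sided hypergeometric
tail with Benjamini-Hochberg and Bonferroni columns — a service-specific
set-counts correction used by some web tools is intentionally not
reimplemented.

Gene-level association aggregates variant z-scores as `T = sum z²` with a
Satterthwaite scaled-chi-square null (`E[T] = m`, `Var[T] = 2 sum R²`),
which is exact for independent variants and invariant to duplicating a
variant in perfect LD. The competitive set test regresses probit-transformed
gene p-values on a membership indicator plus log gene length and log variant
count, one-sided on the indicator. Calibration (type-I error, power under a
z-shift) is the contract; numerical parity with any specific external tool
is not claimed.

## Score construction and evaluation

A PES is `sum_j beta_j G_ij` over variants annotated to the network's genes
under conservative (5 kb up / 1.5 kb down) or liberal (35 kb / 10 kb)
strand-aware genic windows; the genome-wide PRS is the same sum over all
variants. Scores are standardized per scoring cohort (a frozen-moments mode
is available by constructing ScoreVector directly).

**C+T.** Greedy clumping (250 kb window, r² 0.1, PRSice-style defaults —
the clump tie-break everywhere is (p, position, variant_id) for
bit-reproducibility), then thresholding at p in {0.005, 0.05, 0.5, 1}.

**Penalized regression.** The summary-statistic lasso objective

    f(beta) = beta'((1-s)R + sI)beta - 2 beta'r + 2 lambda |beta|_1,
    r = z / sqrt(n),

is minimized by cyclic coordinate descent with warm starts along a
descending 20-point log-spaced lambda grid up to max|r|; s comes from the
a-priori grid {0.2, 0.5, 0.9, 1}. At s = 1 the update is the exact soft
threshold; the objective is asserted non-increasing per sweep in debug mode.
R is built block-wise: contiguous runs split at >250 kb gaps and capped at
256 variants, with off-block LD treated as zero, so memory and per-sweep
cost stay bounded. (s, lambda) are chosen by the highest absolute Pearson
correlation between the training-cohort score and phenotype.

**Model selection.** Per score set, the surface is C+T thresholds x genic
boundaries plus the lasso grid; the winner maximizes training-cohort
liability-scale R². Winners are then rescored in a disjoint validation
split. The 70/30 case split with 2:1 control:case sampling is deterministic
under seed. Penalized models often win in training but can transfer worse
than C+T at small network sizes — the evaluation reports both cohorts, so
this is visible rather than hidden.

**Evaluation.** Logistic regression of case status on the standardized score
with sex, age, batch, and five principal components; Nagelkerke R² is the
increment of the score over the covariate-only model, converted to the
liability scale with

    R²_liab = R²_obs · K(1-K)/z² · K(1-K)/(P(1-P)),

where K is population prevalence, P the sample case proportion, and z the
standard-normal density at the liability threshold. The PRS-adjusted test is
a 1-df residual-deviance chi-square of covariates+PRS+PES over
covariates+PRS (an error if |r(PES, PRS)| > 0.99). Separation triggers a
Jeffreys-penalized (Firth-style) refit, flagged in the result.

Elevated-PES analyses use the top decile of each score (type-7 quantiles;
ties at the threshold count as elevated; decile computed on cases+controls
jointly, controls-only by flag) and the "at least one elevated PES"
indicator; the low-PRS stratum is the lowest PRS decile of the full cohort.
Residualized scores are OLS residuals of the score on PRS, principal
components, and batch, restandardized; a score fully explained by the
regressors is an error, not a silent zero. The pheWAS grid runs linear
models for continuous traits and logistic for binary ones, with FDR and
Bonferroni flags whose threshold is recomputed from the actual score x trait
pair count; sensitivity refits add a PRS covariate, log and
inverse-rank-normal (Blom) outcome transforms, and a statin indicator.
Sex-stratified fits feed the dimorphism contrast
`z = (b_m - b_f)/sqrt(se_m² + se_f²)`.

## Synthetic data: what it emulates and what it does not

Genotypes are drawn per LD block from a latent Gaussian with
compound-symmetry correlation, thresholded per haplotype at the
allele-frequency quantile and summed, giving Hardy-Weinberg dosages in
{0,1,2}. Thresholding attenuates correlation, so the latent value is
arcsine-calibrated (`latent = sin(rho·π/2)`) so that realized genotype
correlation approaches the requested `within_block_rho`; the calibration is
accurate for common alleles and attenuates further at low minor-allele
frequency. All randomness flows through `numpy.random.default_rng` (PCG64),
so outputs are bit-reproducible for a fixed seed and numpy major version.

Phenotypes follow a liability-threshold model: per-gene-set genetic
components built from standardized dosages, each rescaled to its requested
liability variance share, plus Gaussian environment. GWAS summary statistics
come from a per-variant intercept-only logistic score test.

The two planted study designs are fixed as the package's study conditions:

- **Anchor discovery** — ten single-tissue gene models in one locus panel,
  one causal gene carrying 5% of liability (prevalence 0.2, GWAS n = 6,000,
  LD reference n = 800), correct expression weights, one high-confidence
  drug in the risk-reversing direction plus direction/source/gene decoys,
  and decoy QTL instruments that violate each selection rule.
- **Network PES** — six anchor networks of five genes (six variants per
  gene, realized within-block r ~ 0.25) each carrying 1% of liability, a
  diffuse polygenic background of 30% over 640 genes, prevalence 0.10, GWAS
  n = 11,000, and an ascertained target cohort of 2,000 cases / 4,000
  controls drawn from a 24,000-person population. These sizes keep a
  50-seed end-to-end experiment inside a desktop compute budget while
  reproducing the qualitative regime of interest: PRS liability R² around
  8-17%, PES-PRS correlations near 0.15, and roughly half of cases carrying
  at least one elevated network PES.

What passing tests show: the estimators are calibrated and recover planted
effects under an additive, common-variant, single-population architecture
with block-exchangeable LD. What they do not show: robustness to
imputation error, allele-frequency-dependent architectures, population
structure, realistic LD decay, X-chromosome effects, or real
transcriptome-panel noise — none of which the generator emulates.

A note on the low-PRS stratum analysis: with ~600 individuals (and ~75
cases) in the lowest PRS decile, the elevated-PES excess among cases is
directionally present in nearly all seeds but reaches one-sided p < 0.05 in
only ~25-40% of them. This is an intrinsic power limit of the design at
this cohort size, and the end-to-end experiment therefore asserts the
directional excess across seeds while reporting the per-seed significance
rate.

## Degenerate inputs and tie policies

- Duplicate variant IDs, missing covariates, dosages outside [0, 2], and
  malformed columns are validation errors at load time.
- Strand-ambiguous (A/T, C/G) variants are dropped during harmonization
  (frequency-based resolution is deliberately not attempted; switchable).
- Missing genotypes are mean-imputed per variant and flagged.
- A score whose raw values have zero variance is returned unscaled with a
  warning (scaled values all zero) rather than erroring, so degenerate
  fixtures score cleanly; standalone ScoreVector construction still rejects
  zero variance.
- Clumping, lambda grids, and model selection break ties deterministically
  (first in grid order; (p, position, variant_id) for variants).
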