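# Methods

This note documents the statistical models implemented in `rootmap`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Mixed linear model

All three scans (GWAS, TWAS, eGWAS) share one engine: the single-trait
mixed model

    y = X b + u + e,   u ~ N(0, σ²g K),   e ~ N(0, σ²e I)

with `K` the genomic relationship matrix (VanRaden's first formula,
`K = WW′ / 2Σ pⱼ(1−pⱼ)` on mean-imputed, centered dosages). Variance
components are estimated by REML after one eigendecomposition of `K`,
profiling the restricted likelihood over the ratio λ = σ²e/σ²g in
closed form: a 100-point grid on log₁₀λ ∈ [−5, 5] followed by bounded
Brent refinement. The spectral profiled likelihood is verified in the
test suite against a direct dense evaluation of the error-contrast
density. When `K = I` the components are not separately identified and
the optimizer runs to the λ grid boundary; this is recorded as a
warning, and the GLS test then reduces exactly to OLS.

Scans use P3D ("population parameters previously determined"): λ stays
fixed at its null-model optimum for every predictor, while the residual
scale is re-estimated per predictor, giving a t-test on the GLS
coefficient with n − p − 1 degrees of freedom. A full per-predictor
re-optimization (`p3d=False`) is available and is checked against an
independent dense GLS oracle, but P3D is the default everywhere: it is
what the TWAS requires explicitly, and uniformity across the three
scans keeps results comparable. REML is used for the variance
components of the scans; the BIC for covariate-model selection uses the
full ML likelihood at the REML-optimal λ (`BIC = −2ℓ_ML + q·log n`,
q = fixed effects + 2), because ML likelihoods remain comparable across
models with different fixed effects. Whether the original analysis used
REML or ML for the scan nulls is not documented; this split is our
resolution.

Covariate models compared per response: intercept only, four
subpopulation groups, six subpopulation groups (dummy coding drops the
alphabetically first level; ties in BIC break toward fewer parameters).

The candidate-gene ANOVA (`expression ~ dosage + subpopulation`,
additive dosage coding, no interaction) reports the marginal type-II
F-test for the dosage term; the sum-of-squares type was not documented
and type II is the natural marginal choice without interactions.
P-values are floored at 1e−300 before the −log₁₀ transform and flagged
when clipped.

## Genotype preprocessing

- MAF filter: strictly greater than 0.10, computed on the analysis
  sample set.
- LD pruning (r² > 0.99): sliding window anchored at a SNP, spanning
  100 kb (inclusive) in base pairs, advancing by 100 surviving
  variants; within a window, violating pairs drop the lower-MAF member
  (ties: the downstream SNP). The published description mixes a kb span
  with a variant-count step and the source toolkit's exact semantics
  are ambiguous; the parameterization above is fixed and documented,
  and a final cleanup pass guarantees that no surviving pair within
  100 kb exceeds the threshold — which also makes pruning idempotent.
  Small instances are checked against a brute-force greedy oracle.
- Missing dosages are mean-imputed per SNP before the GRM and all
  association tests (common mixed-model practice; the alternative was
  not documented).
- LD decay: mean r² per physical-distance bin over intra-chromosome
  pairs, overall and per subpopulation, no monotone smoothing.

## Expression processing

Fixed stage order, enforced by stage tags: counts → TMM factors → FPKM
→ log₂(FPKM+1) profiles → expressed filter → hidden-factor residuals.

- TMM: reference column is the sample whose upper quartile of nonzero
  counts is closest to the mean upper quartile (ties: lowest index);
  per-gene log-ratios are double-trimmed (30% by M, 5% by A) and
  combined with delta-method inverse-variance weights; factors are
  rescaled to geometric mean 1. FPKM uses effective library sizes
  (column sum × TMM factor); whether the original pipeline scaled by
  raw or effective sizes is not stated, and effective sizes are the
  normalizing tool's own convention.
- Expressed filter: a gene is dropped when its profile is below 1.0 in
  strictly more than 50% of samples.
- Hidden-factor removal: the upstream analysis used a Bayesian ARD
  factor model (PEER) solely to produce k = 5 residuals. Here the
  k-factor linear confounder model is fit by truncated SVD of the
  gene-centered profile matrix (principal factors), preserving the
  contract — k-factor linear confounder removal plus a per-factor
  relevance table for elbow diagnosis — without the ARD machinery.
  This is a deliberate stand-in, not a numerical replica: parity with
  any external implementation is a non-goal. No covariates enter the
  factor model; the risk that factors absorb genotype signal is
  surfaced by a recovery test (planted cis slopes survive
  residualization when factors are genotype-independent) rather than
  prevented.

## Peaks, gene sets, enrichment, colocalization

- Significance throughout: Benjamini–Hochberg FDR-adjusted P strictly
  below 0.10.
- Peak merging is single linkage: significant SNP pairs within 100 kb
  (inclusive) with r² > 0.50 (strict) share a locus, and connected
  components partition the significant set — transitive closure is the
  only partition consistent with pairwise merging. The peak SNP is the
  component's smallest p (ties: smallest position).
- Candidate intervals: gene *spans* intersecting the closed ±250 kb
  window around the peak SNP (intersecting spans rather than gene
  starts was an open reading; spans are inclusive and strictly more
  conservative about exclusion).
- Directional top-1% TWAS lists take floor(0.01 × n_genes) genes per
  sign of the effect, ranked by ascending p within sign (ties: gene
  id); the floor is computed on the full gene count, which reproduces
  the printed 169-of-16,901 denominators. Genes with effect exactly 0
  join neither list. Whether the original ranking was p-within-sign or
  signed-statistic is unspecified; p-within-sign is implemented.
- Enrichment: exact hypergeometric upper tail P(X ≥ k) (scipy's
  survival function; no normal or Poisson approximation — printed
  values down to 5.49 × 10⁻¹³ reproduce to 3 significant figures).
  MSU↔RAP identifier mapping is strictly one-to-one; genes on either
  side of a multi-mapping are dropped and audited. FDR runs across the
  terms actually tested per gene set. The minimum gene-set-size filter
  defaults to 1 (permissive; the upstream tool's default of 10 would
  act as a hidden filter) and is configurable.
- eGWAS uses the expression *profile* as the response (as the source
  analysis describes), with the same BIC model selection; significant
  SNPs within 250 kb (inclusive) of the gene span are cis. When several
  cis SNPs tie at the minimum p, all are retained and the
  nearest-to-gene is the representative. Colocalization compares the
  cis peak with the lowest-p GWAS SNP on the same chromosome (no
  significance requirement on the comparator; its p is reported):
  overlap iff distance < 250 kb (strict) and r² > 0.50 (strict),
  exactly as the two rules are phrased. Trans peaks are reported but
  never colocalized.

## Synthetic cohorts

The generator emulates the study design the analysis assumes:

- 57 samples in four subpopulations (7/19/21/10) by default, with a
  finer six-group labeling obtained by splitting the last group;
  n = 200 (4 × 50) cohorts are used where parameter recovery needs
  statistical power.
- Genotypes: per LD block (default 10 SNPs), 4 founder haplotypes drawn
  around shared ancestral frequencies U(0.05, 0.95); each subpopulation
  receives Dirichlet haplotype frequencies whose spread is set by a
  divergence parameter (default 0.1, zero meaning identical
  frequencies); samples draw two haplotypes per block. This
  block-haplotype model was chosen over coalescent simulation: it is
  simpler, has deterministic block boundaries, and is sufficient to
  exercise pruning, LD decay, and peak merging. Defaults: 10,000 SNPs
  on 4 chromosomes of 30 Mb.
- Expression: log₂-scale truth = baseline U(1,6) + per-sample
  biological variation (sd 0.5) + planted cis effects × dosage;
  observed = truth + 5 hidden factors (loading sd 0.5) + measurement
  noise (sd 0.5). Counts are Poisson draws of log-normally jittered
  rates (negative-binomial-like, jitter sd 0.15) with each sample's
  expected depth pinned to a library size drawn U(5e6, 2e7) — the count
  model itself is unspecified upstream; only the log₂(FPKM+1) pipeline
  downstream matters, so a Poisson–log-normal mixture was chosen for
  simplicity. Planted cis SNPs lie within 100 kb of their gene.
- Phenotypes: trait = Σ gene effects × true expression + Σ SNP effects
  × dosage + polygenic term (MVN with GRM covariance, scaled so its
  share of total variance equals the planned fraction) + independent
  noise of stated absolute variance. Realized variance fractions are
  recorded in the truth file, which suffices to recompute every planted
  quantity without the generator.
- A single integer seed governs all randomness; per-stage substreams
  derive from it via `numpy.random.SeedSequence`.

What passing tests show — and do not. The cohorts reproduce the
*statistical structure* the methods assume (structured relatedness,
block LD, confounded expression, sparse causal architecture). They do
not reproduce real LD complexity (no recombination map), real count
dispersion, indels, or read-level artifacts; planted-signal recovery
therefore validates the pipeline's logic and calibration, not its power
on any particular real dataset.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down cohorts (hundreds to ~2,000
SNPs, 60–200 genes, 57–200 samples), sizes at which every property
checked — calibration, recovery, oracle equivalence — is already
informative while the full suite stays fast. REML refinement tolerance
is 1e−7 on log₁₀λ; kinship PSD tolerance 1e−8; p-value floor 1e−300.
Degenerate inputs (constant predictors, zero-variance LD vectors, empty
significant sets, empty enrichment backgrounds) return missing values
or empty results rather than errors wherever the quantity is undefined
rather than erroneous.

## Known limitations

- The null calibration of mixed-model t-tests is approximate at n = 57
  (the t reference with n − p − 1 df ignores variance-component
  estimation error); the pooled KS check bounds the practical effect.
- The factor model removes exactly k components with no shrinkage, so
  with k larger than the true confounder count it can absorb weak
  genetic signal.
- Stage outputs are written per run; there is no content-hash cache, so
  re-running a late stage re-executes earlier ones. Determinism given
  config + seed is tested instead.
- eGWAS trans peaks are detected but intentionally unused downstream.
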