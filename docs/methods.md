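# Methods

This note documents the statistical models, numerical choices, and the
design decisions behind them. Notation: t traits, n animals; G₀ and R₀
are the t×t trait-level genetic and residual covariance matrices
(kept distinct from the genomic relationship matrix, written G).

## Relationship matrices

**A and A₂₂.** The numerator relationship matrix is built bottom-up by
the tabular method, a_ij = ½(a_i,sire(j) + a_i,dam(j)),
a_jj = 1 + ½·a_sire(j),dam(j), over a topologically sorted pedigree.
Unknown parents are unrelated, non-inbred founders; no genetic groups
are fitted. A is never materialised for a full production-scale
pedigree: subset requests (including A₂₂ for the genotyped animals)
prune the pedigree to the subset plus its ancestors first, which gives
values identical to slicing the full matrix.

**A⁻¹.** Henderson's rules with inbreeding: animal i contributes
1/d_i, −½/d_i and ¼/d_i patterns to the {i, sire, dam} clique, with the
Mendelian-sampling variance d_i = ½ − ¼(F_s + F_d) computed from
parental inbreeding coefficients obtained by a Meuwissen–Luo style
path-tracing evaluation of a_ii (convention: F = −1 for an unknown
parent, so d is 1, ¾ or ½ − ¼(F_s+F_d) for 0/1/2 known parents). Two
independent algorithms therefore produce F — the tabular diagonal and
the path tracer — and the tests require them to agree to 1e−12.

## Genotype QC

The cascade applies animal filters first, then SNP filters, matching
the order in which a lab would triage samples before markers; each
count is local to its stage, so per-category removals reconcile
sequentially.

Animal stages: (1) missing-call fraction > 0.10; (2) no record for any
analysed trait; (3) parent–progeny conflict: a genotyped
parent–offspring pair whose genome-wide opposing-homozygote rate
(AA vs aa at the same SNP) exceeds 0.01; (4) pedigree–genomic
deviation: any pair with |G_ij − A₂₂,ij| > 0.5 under a provisional
VanRaden G computed on the current survivors with mean-imputed missing
calls. For stages 3–4 the package must decide *which* member of a
flagged pair to drop: it removes the member flagged against more
relatives (the likelier mislabelled or contaminated sample), with
pedigree order (the younger animal) as tie-break. The conflict and
deviation thresholds are configurable; the defaults above are design
choices, since these statistics have no universal definition.

SNP stages: unknown map position, sex chromosome, call rate < 0.98,
MAF < 0.01 (both strict — values exactly at a threshold are retained),
and Mendelian error (any surviving genotyped parent–offspring pair with
opposing homozygotes at the SNP; per-SNP tolerance 0). Call rate and
MAF are computed on the surviving animals and on SNPs surviving the
earlier stages.

Residual missing calls are imputed from observed per-SNP allele
frequencies — Binomial(2, p̂_j) draws by default, rounded 2p̂_j in
deterministic mode. Frequency imputation (rather than phased haplotype
imputation) is adequate here because post-QC missingness is at most a
couple of percent per SNP and nothing downstream depends on phase; it
also keeps the pipeline free of external phasing tools.

## Genomic relationships and H⁻¹

G is VanRaden's first form, G = (M − 2p)(M − 2p)′ / 2Σpⱼ(1−pⱼ), with
allele frequencies observed in the genotyped set (a supplied-frequency
mode exists). No rescaling of G toward A₂₂ beyond the α/β blend is
applied by default; compatibility tuning is deliberately left off
because the blend αG + βA₂₂ with α = 0.95, β = 0.05 (weights must sum
to 1) already guarantees invertibility, and the single-step correction

  H⁻¹ = A⁻¹ + [[0, 0], [0, (αG + βA₂₂)⁻¹ − A₂₂⁻¹]]

is stored as the sparse A⁻¹ plus a dense genotyped-block correction.
Dense algebra is used for the genotyped block (thousands of animals at
most), sparse algebra everywhere else. A brute-force oracle test
assembles the joint pedigree–genomic relationship matrix H explicitly
via the standard conditional-Gaussian identity and checks H⁻¹ against
its numerical inverse.

## Phenotypes and stage-1 model

Yearling weight is interpolated to day 365 from the two test weighings:
YW = ((W_t − W_{t−1})/(t − t−1))·(365 − t−1) + W_{t−1}.

Marbling score, a 9-class grade, is treated as a continuous response in
the linear animal model — fidelity to routine practice over measurement
theory; a threshold model is out of scope.

Fixed-effect designs are trait-specific: YW uses
batch–test-place–sex and birth place; carcass traits use
batch–test-place–slaughter-date and birth place with slaughter age
(days) as a covariate, except BT, which omits the covariate.
Identifiability comes from a per-trait intercept with drop-first-level
factor coding; levels absent from the records are dropped
(a non-estimable coefficient would otherwise receive an improper
conditional in the sampler).

**Variance components** are estimated from the multi-trait model
y = Xb + Zu + e, Var(u) = G₀ ⊗ A, Var(e) = R₀ ⊗ I, by a systematic-scan
Gibbs sampler (numba kernel):

1. missing trait records are augmented from the residual conditional
   normal e_m | e_o ~ N(R_mo R_oo⁻¹ e_o, R_mm − R_mo R_oo⁻¹ R_om),
   evaluated per observation pattern, which keeps the G₀/R₀
   conditionals exact;
2. fixed-effect coefficients are sampled one at a time from their
   Gaussian conditionals (flat priors), updating the running residual
   matrix in place;
3. breeding values are sampled animal-by-animal as t-vectors: precision
   a^ii G₀⁻¹ (+ R₀⁻¹ if the animal has a record), using the sparse A⁻¹
   row for the prior conditional mean;
4. G₀ | u ~ IW(ν_g + n, S_g + U′A⁻¹U) and R₀ | e ~ IW(ν_r + n_rec,
   S_r + E′E), drawn by Bartlett decomposition.

Priors are weakly informative: ν = t + 2 and scale = diag(observed
trait variance / 2), so the prior mean equals the scale matrix and
contributes the weight of a single observation against thousands of
records. A data-free run of the sampler reproduces the prior mean (a
prior-recovery test), and a single-trait run is cross-checked against
an independent direct-maximisation REML fit of the same data.

Chain defaults are a desk-scale 110,000 iterations, 10,000 burn-in,
thinning 10 — (110,000 − 10,000)/10 = 10,000 retained samples; the
production-scale configuration of 1,100,000 / 100,000 / 50
(20,000 retained) is available by passing the corresponding settings.
The chain is bit-reproducible given a seed. Convergence is monitored by
a split-chain R̂ on log|G₀| in addition to trace inspection. Posterior
summaries report means and shortest-interval 95% HPDs; heritabilities
and correlations are computed per retained sample and then averaged
(the mean of ratios, not the ratio of means — the two differ on skewed
posteriors and the per-sample convention is asserted by test).

Single-trait mode runs one chain per trait (t = 1), which is exactly
the multi-trait model with all covariances fixed at zero.

**Corrected phenotypes.** y_c = y − Xb̂ = û + ê, with b̂ and û posterior
means from the stage-1 multi-trait fit. y_c is computed once and reused
as the response for all four stage-2 models. The kernel also
accumulates the posterior-mean residuals independently of b̂ and û, so
the identity y_c = û + ê doubles as a consistency check on the
sampler's incremental residual bookkeeping.

## Stage-2 evaluation models

The stage-2 model is y_c = 1μ + Zu + e with a per-trait overall mean as
the only fixed effect (y_c is already corrected). The mixed-model
equations use observation-pattern blocks of R₀ for records with missing
traits (exact, no imputation at this stage) and K⁻¹ ⊗ G₀⁻¹ on the
breeding-value block, with K⁻¹ = A⁻¹ (BLUP) or H⁻¹ (ssGBLUP); unknowns
are ordered animal-major so the Kronecker structure is literal. Systems
are solved by sparse LU by default, with a Jacobi-preconditioned
conjugate-gradient alternative for very large systems; the two agree to
1e−6 by test. Two structural identities pin the implementation down:
multi-trait with diagonal G₀/R₀ reproduces single-trait results, and
ssGBLUP with G := A₂₂ reproduces BLUP exactly.

## Validation

Genotyped animals are clustered into k = 5 folds by K-means on the rows
of A₂₂ (Euclidean distance, best of 25 restarts, fixed seed). Rows of
A₂₂ are the natural finite embedding of "pedigree relationship
coefficients" for clustering; fold = cluster, so validation sets are
family blocks rather than random samples, which prevents close
relatives from standing on both sides of the split. Per fold, all trait
records of validation animals are masked, each model refit, and per
trait: predictive ability r = cor(prediction, held-out y_c); accuracy
r/√h² with h² the stage-1 multi-trait posterior mean, fixed across
folds; bias as the OLS slope of y_c on the prediction. Summaries are
fold means with SE = SD/√k. A permutation null (r against shuffled
y_c) centres on zero by test.

The reduced-records experiment subsamples the abundant trait's records
(uniformly, seeded) down to the scarce trait's count, refits everything
with the validation sets unchanged (training uses the thinned table;
scoring uses the original held-out values), and reports paired
full-vs-reduced metric tables.

## Synthetic data

The generator emulates a progeny-test population: discrete generations,
a limited sire set per generation (paternal half-sib families), random
mating; SNPs are gene-dropped (founders under HWE at Uniform(0.05, 0.5)
frequencies, one allele inherited from each parent, independent loci).
Linkage disequilibrium is deliberately not simulated: the pipeline's
targets are relationship-matrix machinery and variance-component
estimation, neither of which depends on LD, and unlinked loci keep the
generator transparent.

Default trait truths are the five-trait multi-trait covariance
estimates quoted in the README (genetic variances 5.66, 460.32, 29.38,
1.59, 273.81; residual 5.54, 721.79, 35.52, 0.91, 761.44; genetic
correlations including r_G(CW, YW) = 0.76), with residual covariances
derived as phenotypic minus genetic covariance; both matrices are
verified positive definite at import. Phenotypes are
y = fixed effects + u + e with contemporary-group effects drawn at an
SD comparable to the trait's phenotypic SD (stage-1 correction is then
a real task, not a formality), YW on every animal, carcass traits on a
1/2.6 subset and MS on a further 0.685 fraction of those (mirroring the
exclusion of scores from a superseded grading scale). Slaughter age
affects CW/EMA/MS. True breeding values are kept in the table (tbv_*
columns) for validation studies.

Two genetic architectures:

* **polygenic** (default): u by pedigree recursion,
  u_i = ½(u_s + u_d) + m_i, Var(m_i) = ½(1 − (F_s + F_d)/2)·G₀ — exactly
  the Var(u) = G₀ ⊗ A model the Gibbs sampler assumes, hence the
  architecture used for parameter-recovery verification.
* **genomic**: u = Za with per-SNP effect vectors
  a_j ~ MVN(0, G₀ / 2Σp(1−p)), so realized genomic relationships carry
  Mendelian-sampling information. This is the architecture under which
  single-step evaluation genuinely outranks pedigree BLUP; under the
  polygenic architecture marker relationships are, by construction,
  pure noise around A with respect to u, and ssGBLUP cannot win — a
  property worth knowing when interpreting any simulation study of this
  design. Directional model comparisons in the tests therefore use the
  genomic architecture.

What passing tests on these data do *not* show about real data: no LD
(so marker density beyond a few thousand adds nothing here, unlike real
chips), no selection (real progeny-test data are selected, which
ssGBLUP partly corrects for), no genotyping error, random rather than
criterion-based slaughter subsets, and contemporary groups assigned at
random rather than by calendar structure.

The QC fixture engineers a 45,304-SNP × 1,679-animal panel whose
cascade removes exactly 302 / 1,150 / 2,677 / 6,684 / 12 SNPs and
73 / 15 / 11 / 39 animals (each category disjoint at its stage by
construction: 15% missingness for high-missing animals; conflict
progeny with opposing homozygotes planted at 2% of SNPs; deviation
animals as pedigree full sibs carrying mirrored genotypes 2 − g; twelve
Mendelian-error SNPs planted in one surviving parent–child pair),
leaving 34,479 SNPs and 1,541 animals.

## Problem sizes and numerical notes

Verification runs use a ~3,000-animal, five-generation pedigree with a
110,000-iteration chain for parameter recovery (minutes on one CPU; the
kernel is O(iterations × animals × t²)), and 30–500-animal instances
for the exact-oracle tests. Tolerances: relationship-matrix oracles at
1e−12 (pure arithmetic), A⁻¹·A and MME-vs-GLS at 1e−8 (sparse solves),
H⁻¹ brute force at 1e−6 (two nested inversions). K-means folds and all
simulations are seeded; the Gibbs kernel seeds numba's RNG, so chains
are reproducible bit for bit within a numba version. Degenerate inputs
are errors, not warnings: monomorphic-only panels (zero G scale),
singular blended G, non-PD covariance inputs, cycles or duplicate ids
in pedigrees, SNPs with zero observed calls at imputation.

## Known limitations

Marbling score is modelled as Gaussian. No genetic groups or
metafounders for unknown-parent structure. No APY or other large-n
approximations of H⁻¹ (dense genotyped block assumed to fit in memory).
The reduced-records subsample is uniform over recorded animals rather
than stratified by cohort. Inverse-Wishart hyperparameters are weakly
informative defaults; sensitivity beyond the prior-recovery and
REML-agreement tests has not been mapped.
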