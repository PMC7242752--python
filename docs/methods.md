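# Methods

## Model and assumptions

The engine works in the single-variant linear-model world: for a
mean-centered genotype dosage *x* and mean-centered traits
**y** = (y₁,…,y_k), the model is x = yᵀβ + ε with Gaussian ε. Under this
model the first canonical correlation between the variant and the trait
set equals √R² of regressing *x* on **y**, and the maximized log-likelihood
is an affine function of log(1 − R²). Everything the pipeline reports —
r₁, P, BIC — is a deterministic function of (i) the per-trait z-scores and
sample sizes and (ii) the trait correlation matrix S_YY:

- r_j = z_j / √(n_j + z_j²) (sign-preserving square root of the
  single-trait R² = 1/(1 + n/z²); this is the large-n form of the exact
  OLS identity R² = z²/(z² + n − 2), and the residual-df difference is
  O(1/n) in R²);
- r₁ = √(rᵀ S_YY⁻¹ r), solved by Cholesky factorisation of the subset
  block (never an explicit inverse), clipped to [0, 1 − 10⁻¹²] so logs
  stay finite under numerical noise;
- P from F = (R²/k)/((1 − R²)/(n − k − 1)) ~ F(k, n−k−1), which is exact
  for this model. `--pvalue-method bartlett` instead refers
  −(n − 1 − (k+2)/2)·ln(1 − R²) to χ²_k; the two agree closely for large
  n and the F form is the default because it is exact where the
  derivation lives;
- BIC = k·log n + n·log(1 − R²). The additive constant −2·loglik of the
  null model is independent of the subset and is dropped; only BIC
  *differences* are ever interpreted.

Assumptions inherited from this derivation: one variant at a time (the
genotype-side correlation matrix is the scalar 1, so LD between variants
never enters), quantitative traits analysed by OLS without covariates, and
a shared (or at least overlapping) study population so that
effect-estimate correlations across variants estimate the phenotypic
correlations.

## Trait correlation matrix

S_YY is estimated as the Pearson correlation of the per-trait effect
estimate columns over all harmonised variants. Under the null the
sampling correlation of two traits' effect estimates equals the trait
correlation, and genuinely associated variants are a vanishing fraction of
a genome-wide panel; `--corr-exclude-significant` re-estimates without
them for small panels, and `--trait-corr FILE` accepts a user-supplied
matrix (validated for symmetry, unit diagonal and |ρ| ≤ 1). A warning is
emitted below 1,000 variants, where the 1/√M sampling error becomes
non-negligible.

`--metacca-plus` multiplies all off-diagonal entries by `--shrink-step`
(default 0.999) until the smallest eigenvalue reaches `--eigen-floor`
(default 10⁻⁴). Multiplicative shrinkage is monotone and convergent (the
identity limit always satisfies any floor ≤ 1); the iteration count is
recorded. The floor comparison carries a 10⁻⁹ relative slack so that
matrices whose exact minimum eigenvalue equals the floor are not shrunk on
account of eigensolver rounding.

## P-values on the −log10 scale

All P-values are computed and carried as −log₁₀P. The F and χ² upper
tails use scipy's log survival functions; where those underflow to −∞
(multivariate P-values below ~10⁻³⁰⁰ occur routinely at strong loci) the
leading term of the incomplete-beta (respectively incomplete-gamma)
expansion takes over, so the statistic remains finite and strictly
monotone in r₁ arbitrarily far into the tail.

## Scan, significance, clumping

The full K-trait model is scored for every variant. Chunks are processed
through a per-variant scalar path (quadratic form via a precomputed
S_YY⁻¹), so results are bitwise identical for any `--chunk-size` /
`--threads` combination; worker processes each handle an independent
chunk and the merge preserves panel order. Significance is P < the
`--p-threshold` (default 5×10⁻⁸). Clumping is greedy by ascending P
(ties broken by chromosome, position, id): each new lead absorbs all
remaining significant variants on the same chromosome within
`--clump-kb` (default 1,000 kb) of it, so leads are pairwise separated by
more than the window. Removal is lead-to-member, the standard practice;
the subset sample size for a trait subset is the per-variant minimum over
member traits (`--n-policy min`, conservative under per-trait
missingness) or the rounded mean (`mean`).

## Decomposition

From the full model, one trait is removed per step until a single trait
remains. At each step all current-size-minus-one subsets are scored; the
highest trace keeps the maximum-r₁ subset, the lowest trace the minimum.
Single-trait subsets are scored through the same R²-from-z path, so the
traces genuinely extend to size 1. Two candidates whose r₁ agree within
10⁻¹² are tied; the tie drops the lexicographically smallest trait name,
making the output deterministic (for highly correlated traits the drop
order near a tie is not statistically meaningful, only reproducible). A
per-variant memo cache scores each distinct subset once; at K = 21 the
three traces touch ~445 unique subsets (≤ K² + K), versus 2²¹ − 1 =
2,097,151 for exhaustive search.

- **Drivers**: walking the lowest trace from the full model, the traits
  dropped up to and including the first step whose P-value is no longer
  below the threshold; the reported "P without drivers" is that step's.
  If even the final single-trait subset stays significant, all K traits
  are drivers and the P is reported as NA. A full model that is itself
  not significant (custom variants) has no drivers, with a warning.
- **Optimal set**: minimum-BIC subset over all subsets on the highest
  trace, all subsets on the inverted lowest trace (the cumulative drop
  sets, which include every prospective driver set) and the full model;
  ties prefer the smaller subset, then lexicographic order. The greedy
  pool is not guaranteed to contain the global 2^K optimum;
  `exhaustive_minimum_bic` provides the brute-force reference for K ≤ 12
  and is used as the test oracle.
- **Central traits**: the union of drivers and the optimal set.

## Reporting

Per lead variant: a P-value trace plot (−log₁₀P of the three traces
against subset size, threshold line), a BIC trace plot (negative BIC,
optimum starred) and a univariate bar plot (per-trait −log₁₀P, colored by
effect direction). Across leads: a trait-importance heatmap — the lowest-
trace drop rank transformed to (K − rank)/(K − 1), so the first-dropped
(most irreplaceable) trait scores 1.0 and the survivor 0.0 — clustered
with average-linkage hierarchical clustering on Euclidean distances
(deterministic given input order), and a variant-similarity heatmap of
Spearman rank correlations between drop-rank vectors (needs ≥ 2 leads).
Every plotted number is also written as a TSV; plots are views, never the
only record.

## Synthetic data generator

`simulate` draws independent biallelic dosages ~ Binomial(2, maf) with
maf ~ U(maf_range), traits as multivariate normal noise with a target
correlation matrix (exchangeable ρ or explicit K×K) plus planted
per-allele effects in trait-SD units, and optional uniform per-trait
missingness; `summarize` reduces them to per-trait simple-regression
summary statistics (slope, standard error with residual df n − 2,
non-missing n), exactly the input contract of the pipeline. Defaults —
2,000 individuals, 5,000 variants, 8 traits, ρ = 0.4, maf ∈ (0.05, 0.5) —
emulate a small deeply-phenotyped cohort and run in seconds. All
randomness flows through one seeded generator; identical configs are
bit-identical.

What the generator deliberately omits, and what passing tests therefore
do not demonstrate: linkage disequilibrium (clumping windows here absorb
chance proximity, not LD structure), population stratification and
relatedness, covariate-adjusted or binary traits, and non-Gaussian trait
distributions. The individual-level oracle (`oracle_subset_stats`:
direct OLS R², maximized-likelihood BIC, exact F P-value) is the ground
truth for all engine validation.

### Recovery scenarios

For parameter-recovery experiments ("the optimal set equals the planted
traits"), the planted truth must actually be the population-optimal
model. With noise correlation between affected and unaffected traits the
unaffected traits genuinely improve the regression of genotype on traits
(they explain correlated noise), and with strong correlation among
affected traits their marginal contributions become partially redundant —
in both cases BIC is *right* not to return the planted set. The recovery
scenario therefore plants equal effects (0.22 SD/allele) on three
mutually independent traits, independent of an exchangeable (ρ = 0.4)
null block, at maf ∈ (0.3, 0.5) and n = 2,000: each planted trait then
contributes a marginal deviance of ≈ 40 against a penalty of log n ≈ 7.6,
which a 90% recovery bar comfortably tolerates.

## Numerical choices

- r₁ clipped at 1 − 10⁻¹²; quadratic forms clipped into [0, (1−10⁻¹²)²].
- Symmetric solves via `cho_factor`/`cho_solve`; a non-PD subset block
  raises an error directing the user to `--metacca-plus`.
- Degenerate inputs: monomorphic variants are dropped at summary time;
  duplicated trait columns make the subset block singular (see above) or,
  after shrinkage, are dropped first on the highest trace at ~zero R²
  cost; n ≤ k + 1 is a hard error.
- TSV outputs use a fixed float format, so identical configs and inputs
  reproduce byte-identical tables.

## Known limitations

Sequential one-trait-at-a-time elimination does not guarantee the global
BIC optimum (the exhaustive oracle agrees with the trace optimum in most
but not all random scenarios); driver sets depend on a fixed significance
threshold and claim no optimality; S_YY estimated from effect estimates
assumes a single study (sample-overlap structure beyond that is not
modelled); and the method is single-variant — no conditional analysis,
no LD-aware clumping, no S_XX ≠ 1 multi-variant canonical correlation.
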