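# Methods

## Setting

A case-parents (trio) study genotypes an affected child and both parents
at `L` biallelic variants in a gene region.  For each variant one allele
is designated *mutant* — by default the minor allele among the parental
chromosomes, so that ascertainment of affected children cannot flip the
label.  The data reduce, per family `i` and variant `j`, to the signed
transmission difference `X_ij = 2 g_child − g_father − g_mother` and the
heterozygous-parent count `het_ij ∈ {0,1,2}`; per variant, `H_j = Σ_i
het_ij` and the transmitted count from heterozygous parents `b_j = (H_j +
Σ_i X_ij)/2`.  Homozygous parents are uninformative.  Conditional on
`H_j`, `b_j` is Binomial(`H_j`, `p_j`); `p_j = 1/2` exactly when the
variant is neither linked nor associated, *regardless of population
structure* — the property that makes every test here stratification-robust.

## Transmission probability under a disease model

For a variant with MAF `q`, genotype relative risk `r` and inheritance
form (dominant / multiplicative / recessive), the probability that a
heterozygous parent of an affected child transmitted the mutant allele is
obtained by enumeration over Hardy–Weinberg mating types: the focal
heterozygous parent transmits each allele with probability 1/2; the other
parent transmits a mutant allele with marginal probability `q` under HWE;
the child is affected with penetrance proportional to the form's weight
`w(g)` (baseline cancels).  This gives

    p(q, r) = b1 / (b1 + b2),
    b1 = ½[(1−q) w(1) + q w(2)],   b2 = ½[(1−q) w(0) + q w(1)],

which equals 1/2 at `r = 1` for every `q` and form, and tends to
`r/(1+r)` as `q → 0` under the dominant model.  The implementation is
validated in the tests against a Monte-Carlo oracle that simulates 10⁶
ascertained trios directly.

## The random-effects mixture LRT

With a relative-risk ceiling `γ` (default 5; a value that is deliberately
generous unless prior information justifies a tighter bound), the
transmission probability of a deleterious functional variant is confined
to `(1/2, δ_j]` with `δ_j = p(q̂_j, γ)` under the dominant form.  The MAF
estimate `q̂_j` is the parental allele frequency over the `4n` parental
chromosomes, clamped to `[1/(4n+2), 1 − 1/(4n+2)]`; parental quantities
are invariant under the permutation null, so `δ_j` is computed once per
cohort.  `δ_j` decreases in `q̂_j` — rarer variants are allowed larger
effects, matching the usual frequency–effect-size relationship.

Modelling `p_j` as a random effect — point mass at 1/2 with probability
`1 − π`, Uniform(1/2, δ_j) with probability `π` — the marginal of the
transmitted count is

    P(T_j = t | H_j) = (1−π) C(H,t) 2^{−H}
                     + π [F_δ(t+1, H−t+1) − F_{1/2}(t+1, H−t+1)] / ((H+1)(δ−1/2)),

where `F_x(a, b)` is the regularized incomplete beta function; the second
term uses the identity `C(H,t) B(t+1, H−t+1) = 1/(H+1)`.  The pmf is
evaluated in log space and is stable at least to `H = 10⁴`; its
normalization and agreement with numerical quadrature of the binomial
over the uniform mixing density are asserted to 1e−12 / 1e−10 in tests.

The per-variant marginals are multiplied into a *pseudo*-likelihood
(transmitted counts across variants need not be independent), and
`Λ = 2 log L(π̂) − 2 log L(0)` tests the boundary hypothesis `π = 0`.
Because each term is the logarithm of a function linear in `π`, the
profile is concave on [0,1]; the public `fit_pi` uses a 0.01 grid plus
bounded refinement (tolerance 1e−6, boundary values admissible), while
the permutation engine solves the first-order condition by vectorized
bisection — the two agree to the optimizer tolerance by construction and
by test.  `Λ` does not have a usable asymptotic null distribution here
(boundary parameter, pseudo-likelihood), so its p-value comes from the
permutation null like the other tests.

## Permutation null

Within each family an independent fair coin either keeps the child's
transmitted genotype vector or swaps it with its complement
`g_f + g_m − g_c`, i.e. multiplies the whole row `X_i` by ±1.  The swap is
applied at the family level across all variants jointly: it preserves
`H_j` and all cross-variant dependence, and it is the only version
computable from genotypes alone (per-parent flips would require phase
when both parents are heterozygous, and phase-ambiguous trios contribute
`b = c = 1` automatically in the `X` formulation).  The p-value is the
add-one estimator `(1 + #{Λ_perm ≥ Λ_obs}) / (1 + n_perm)` — always
positive, valid as a permutation p-value, and deterministic given the
seed.  Within one analysis the same flip matrix serves all four tests;
each marginal p-value is exact, and the shared stream saves most of the
compute.  The observed statistic is evaluated by the same vectorized code
path as the permuted ones so that numerical ties are counted
consistently.

The asymptotic chi-square p-value for the multivariable statistic
(df = rank of `V`) is kept as a diagnostic only; it is conservative for
more than a few markers.

## Simulator

The generator reproduces the evaluation design: rare-variant MAFs drawn
uniformly on [0.001, 0.01]; optional common variants at fixed MAFs (3%,
5%); functional relative risks assigned by linear interpolation between
`rr_max` (at the smallest functional MAF) and `rr_min` (at the largest),
the minimal rule consistent with "rarer variant, larger effect" within a
fixed RR range — a single functional variant gets the midpoint; each
functional RR independently inverted with probability `protective_prob`;
disease risk multiplicative across variants with a configurable
per-variant form.  The default per-variant form is dominant; at these
allele frequencies mutant homozygotes are vanishingly rare, so dominant
and multiplicative are practically indistinguishable (both are
implemented and recorded in every result file).  The baseline penetrance
solves `f0 Π_j E[w_j] = prevalence` exactly under independent sites, and
ascertainment is plain rejection sampling on the affected child, so the
acceptance rate equals the prevalence (default 1%).

Configurations with many strong variants can make the nominal penetrance
`f0 Π w_j` exceed 1 for children carrying mutants at nearly every variant
— genotypes of probability ~1e−20 in realistic designs.  Rather than
reject such configurations outright, the simulator clips penetrance at 1
and refuses only when a Chernoff bound on P(penetrance > 1) for a random
child exceeds 1e−6; this keeps the standard evaluation designs valid while
catching genuinely inconsistent settings.

The stratified null mixes two populations at the family level (no
admixed matings): population 2 (20% of families by default) has its own
MAFs (drawn on [0.001, 0.03]) and prevalence (4% vs 1%).  Under the null,
disease is independent of genotype, so ascertainment is Bernoulli per
population.

What the generator does *not* emulate: linkage disequilibrium and a
coalescent site-frequency spectrum.  Sites are independent and rare MAFs
are uniform on their range, which yields a somewhat higher mean MAF (and
hence more heterozygous parents per variant) than a coalescent spectrum
restricted to the same range, and no LD between variants.  An explicit
haplotype-pool hook (`simulate_trio_cohort(..., pool=...)`) accepts any
(n_haplotypes × L) 0/1 matrix — e.g. coalescent output — in place of the
parametric parents, leaving everything downstream unchanged.
Consequently, passing calibration tests here demonstrates correct type I
error (which conditions on parental genotypes and is insensitive to the
frequency spectrum) and the qualitative power ordering of the tests;
absolute power in weak-signal, many-variant designs runs above what a
coalescent pool gives, because power there is driven by the per-variant
count of heterozygous parents.

## Numerical and design choices

* Mendelian consistency is enforced on cohort construction via the
  interval check `child ∈ [(f=2)+(m=2), (f≥1)+(m≥1)]`; violations are
  errors naming family and variant, never silently corrected.  Families
  with any missing genotype are dropped and counted (the tests and the
  family-level swap need complete per-family vectors).
* Pseudo-inverse cutoff for `V` is numpy's default (singular values below
  `max(L,n)·eps·σ_max`); rank deficiency is the normal state with rare
  variants and duplicated or empty columns are handled exactly.
* Uninformative inputs: `(b−c)²/(b+c)` is defined as 0 when `b+c = 0`;
  variants with `H_j = 0` contribute 0 to the pseudo-log-likelihood; a
  cohort with no informative variant at all is an error for the LRT.
* Mixture-component underflow (`F_δ − F_{1/2}` ≈ 0 for `t ≪ H/2` at large
  `H`) is clipped at 1e−300; the likelihood ratio per variant is clipped
  to `exp(±700)` before the concave solve.
* Replicate seeding uses `SeedSequence(master).spawn(n_reps)`, so
  experiment results are bit-identical for any worker count.
* Experiment scale defaults to 500 replicates × 1000 permutations (the
  acceptance script uses 500×1000, with 300 replicates for the 1000-trio
  design and 400 for the stratified null); the test suite uses 80–150
  replicates × 400 permutations per design.  Monte-Carlo standard errors
  are reported alongside every rate, and tolerance bands scale with the
  replicate count actually used.

## Limitations

* Complete trios only: no missing-parent designs, sibling designs, EM
  imputation, or general pedigrees.
* No variant weighting (frequency-based or functional-annotation-based)
  beyond the MAF-dependent `δ_j` bound that is intrinsic to the mixture
  model; no variable-threshold analysis.
* Power under the recessive model is intrinsically poor at these allele
  frequencies (mutant homozygotes are rare); the simulator supports the
  form but no claims are made for it.
* `π̂` is a point estimate from a pseudo-likelihood; no confidence
  intervals or per-variant effect estimates are provided.
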