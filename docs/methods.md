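# Methods

## The model

Every analysis assumes the standard linear model for a balanced
line × tester testcross trial evaluated in *e* environments with *r*
replicates arranged in resolvable incomplete blocks:

```
y = µ + g_i + g_j + s_ij + E_k + R_l(k) + B_m(kl)
      + (gE)_ik + (tE)_jk + (sE)_ijk + ε
```

with lines, testers and their interaction fixed in the ANOVA sense
(hybrids are the objects of inference) and environment, replicate,
block and all ×environment interactions random.  Effects are identified
by the sum-to-zero convention: GCA vectors sum to zero, the SCA matrix
has zero row and column sums.

Checks and the inter-tester hybrid T1×T2 contribute to the Hybrid and
Hybrid×Env strata but are excluded from the Line/Tester/Line×Tester
partition, which is computed among the l·t testcrosses only.

### Sums of squares and the lattice blocks

Under balance all listed strata except the incomplete blocks are
mutually orthogonal, so their sums of squares are closed-form contrasts
of group means.  The lattice blocks are **not** orthogonal to entries;
they are fitted sequentially *after* all entry terms (intra-block
adjustment): the block dummies are projected off the entry-mean and
replicate strata and the residual sum of squares is split into a
Block(Env:Rep) stratum of `Σ (n_blocks − 1)` df and a pure Error.  The
genetic mean squares are therefore identical with and without blocking
(verified by test); blocking only purifies the error term.  A
mixed-model lattice adjustment of entry means is intentionally out of
scope — the published table structure is the target, not any particular
mixed-model solver.

A trait scored in a subset of environments (carotenoids are typically
assayed in fewer locations than agronomic traits) is analysed over the
environments where it has data.  Any *partially* missing
testcross × environment cell aborts the ANOVA with the offending cells
named; no imputation is performed, because the estimators below are
derived for balanced data.

### F tests

Environments are random, so each genetic source is tested against its
own ×Env interaction: Line vs Line×Env, Tester vs Tester×Env,
Line×Tester vs Line×Tester×Env, Hybrid vs Hybrid×Env, and Testcross vs
the pooled testcross×Env mean square (the three interaction rows pooled,
whose df add up exactly).  Design strata and the ×Env interactions are
tested against the pooled error.  Significance is rendered `*`/`**` at
0.05/0.01.

### Variance components (method of moments)

Equating observed to expected mean squares of the balanced design gives

```
v_sca        = (MS_LxT − MS_LxTxE) / (r e)
v_gca_line   = (MS_L   − MS_LxE)   / (r e t)
v_gca_tester = (MS_T   − MS_TxE)   / (r e l)
v_line_env   = (MS_LxE   − MS_err) / (r t)
v_tester_env = (MS_TxE   − MS_err) / (r l)
v_sca_env    = (MS_LxTxE − MS_err) / r
v_residual   =  MS_err
```

Negative estimates are truncated to zero for reporting and flagged,
never silently; the raw (unbiased) estimates remain available and are
what the recovery tests compare with truth, since truncation biases a
bias check (most visibly for the tester component, whose mean square has
a single df).  Standard errors use the large-sample variance of a linear
combination of independent mean squares, `Var(MS) ≈ 2 MS²/(df+2)`.
A REML refinement would target the same estimands on balanced data and
is deliberately not implemented; closed form keeps every number
oracle-testable.

Derived summaries: CV% = 100·√MS_err/mean; Baker's ratio
`2(MS_L + MS_T) / (2(MS_L + MS_T) + MS_SCA)` (the combined GCA mean
square enters as MS_L + MS_T); entry-mean repeatability
`H = v_g/(v_g + v_g×e/e + v_res/(er))` with `v_g` the sum of the three
genetic components and `v_g×e` of the three interaction components —
repeatability formulas differ across programs, and this entry-mean
broad-sense form is the package's documented choice.  Proportional
contributions of line/tester/line×tester are reported under two labelled
definitions — shares of the testcross sum of squares (additive, sums to
100 %) and shares of the genetic variance components — because the two
answer different questions and published reports do not always say which
they use.

### Combining ability

On a complete matrix of pooled testcross means the constrained
least-squares estimates are the marginal deviations
(`g_i = row mean − grand`, `s_ij = cell − row − column + grand`);
equivalence with explicit constrained least squares is enforced by test
at 1e−10.  Pooled means are plot-level means by default (identical to
means of environment means under balance; both conventions are exposed
for unbalanced summaries).  Standard errors use the random-environment
denominators, `se(g_line) = √(MS_LxE/(r e t))` etc., with the
denominator's df for the t test.  For t = 2 the SCA significance test is
conservative: each SCA row sums to zero, so the effective spread of
`s_ij/se` is `(1−1/l)(1−1/t)` of nominal.  The additive/non-additive
partition is `2(v_gca_line + v_gca_tester)` vs `v_sca`, as percentages.

### Heterosis and check comparison

Standard heterosis is `100·(F1 − CK)/CK` with the T1×T2 testcross as CK.
Comparisons against a check use a two-sided LSD
`t_{1−α/2,df_err}·√(2 MS_err/(re))` from the combined-analysis error
term, without multiplicity correction — matching the star-only reporting
convention of testcross trials; its per-entry type-I rate is verified at
the nominal 5 % by simulation.

### Correlations and tester evaluation

Phenotypic correlations are product-moment correlations of pooled
testcross means.  Genotypic correlations are method-of-moments:
`cov_g(x,y) = (v_g(x+y) − v_g(x) − v_g(y))/2` using untruncated
components, which on balanced data equals the direct mean-cross-product
estimator (asserted at 1e−8).  Estimates can fall outside [−1, 1] in
noisy data; they are reported as computed with an out-of-bounds flag.
Traits measured in different environment subsets are correlated over
their common environments.  Per-tester genetic variances come from a
one-way line × environment analysis of each tester's testcrosses,
`v_g = (MS_line − MS_line×env)/(re)`, with the standard large-sample SE;
under the sum-to-zero SCA convention this estimates
`v_line + (1 − 1/t)·v_sca`.

## The synthetic generator

`simulate_trial` draws every effect independently Gaussian at its
configured variance, then centres main-effect vectors to exact zero sums
and interaction effects over their genetic margins **within each
environment slice**.  This convention makes the expected-mean-square
identities above exactly unbiased under the generator (centring across
environments instead would bias e.g. v_sca by v_sca×e/e) and makes the
stored ground truth identifiable for recovery tests.  Scores
(plant/ear aspect) are latent Gaussians clipped to [1, 5] and analysed
as continuous, as testcross ANOVAs do.  The layout is a randomized
resolvable incomplete-block design (entries permuted into n/k blocks of
k per replicate, re-randomized per replicate and environment) — the
randomization structure of an alpha-lattice without its efficiency
optimisation, which the intra-block analysis does not require.

Carotenoids are generated through a latent **total-carotenoid** trait
with the same linear structure, split into lutein, zeaxanthin,
β-cryptoxanthin, α-carotene and β-carotene by per-genotype branch
proportions: each tester contributes a fixed compound profile (the
high-PVA tester rich in the β-branch, the low-PVA tester in
xanthophylls), each line adds a small log-scale jitter, and a small
per-compound residual is added on top.  Provitamin A and total
carotenoid columns are then *derived* from the compound columns, so the
defining identities hold exactly in every generated book.  The line GCA
for total carotenoid is `δ·g_yield + independent part`, with the
dilution coefficient δ = −0.0037 (µg/g per kg/ha) chosen so the expected
genotypic yield–PVA correlation is ≈ −0.25, the classic dilution effect;
with the default components this allocates about 12 % of the line
variance in total carotenoid to the yield link.

### Default conditions

The default configuration emulates a tropical PVA testcross program:
60 lines × 2 testers plus T1×T2 and 3 commercial checks (124 entries) in
a 31 × 4 lattice with 2 replicates; agronomic traits in 8 environments,
carotenoids in the first 4.  Trait means and the environment, block and
residual variances were set from the magnitudes such trials print
(grain yield ≈ 6.2 t/ha with CV ≈ 17 %, anthesis ≈ 57 d with CV ≈ 2 %,
PVA means of 10–13 µg/g with CV ≈ 10 %), back-solved through the
expected-mean-square identities.  Genetic components keep SCA variance
well below GCA variance (yield: v_line = 250 000, v_tester = 12 000,
v_sca = 30 000 (kg/ha)²), the additive-dominant regime typical of
carotenoid and yield inheritance in these materials; the implied
additive share is ≈ 94 % for yield and the entry-mean repeatabilities
fall in the 0.7–0.9 range the designs are built to achieve.  Tester
compound profiles give testcross PVA means of ≈ 12.7 (T1) and
≈ 10.2 µg/g (T2).

What the generator does **not** emulate: spatial field trend beyond
blocks, non-Gaussian errors and outliers, unbalanced lattices or lost
plots, genotype-specific error variances, and marker-level genetics.
Passing recovery tests therefore demonstrate estimator correctness under
the stated model, not robustness to those departures.

## Numerical choices

- Field books round-trip bit-identically: values are written with the
  shortest round-trip representation and parsed with correctly rounded
  string→double conversion; missing cells are empty fields, never zero.
- Report tables apply one global rounding rule (half-even, two decimals
  by default); the renderer never recomputes, it only rounds module
  outputs.
- Undefined statistics (zero denominators, all-zero components) raise
  `UndefinedStatisticError` rather than returning silent NaN; truncation
  and out-of-bounds conditions are flagged on the result objects.
- Degenerate inputs: single-environment books drop the ×Env rows and
  test effects against pooled error for SEs; a single replicate without
  blocking has no error stratum and aborts.
- The problem sizes used by the validation suite — 200 simulations at
  the default 60×2×8×2 scale for recovery, 500 null replicates at
  40 lines × 4 environments for F-test calibration, 100 simulations for
  the correlation calibration — were chosen to bound the Monte-Carlo
  standard errors well below the assertion tolerances.

## Known limitations

- Only balanced books are analysed end-to-end; unbalanced data abort
  with named cells rather than being adjusted or imputed.
- Variance-component SEs are large-sample approximations; with t = 2 the
  tester mean square has one df and its component is extremely noisy
  (truncation flags fire under the null about half the time).
- The lattice blocks enter only as an error-purifying stratum; no
  inter-block information recovery.
- Reciprocal effects are not modelled (testcross seed is assumed bulked
  across reciprocals), and no diallel-specific methods are provided.
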