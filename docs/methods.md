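# Methods

## Model and sampling framework

The package works under the standard single-trait animal model

    y = X b + Z u + e,   u ~ N(0, A σ²_g),   e ~ N(0, I σ²_e),

with `A` the pedigree-based numerator relationship matrix and `b` fixed
effects (one or more categorical factors). Predictions are BLUP solutions of
Henderson's mixed model equations; `λ = σ²_e / σ²_g` and variance components
are treated as known. Validation by truncation removes the phenotypes of a
focal cohort and compares the partial-data EBV `û_p` with the whole-data EBV
`û_w` (LR method) or with adjusted phenotypes `y*` (predictivity).

All uncertainty statements are frequentist over repeated sampling of the
phenotypes. Under joint normality, random mating and **no selection**, the
focal EBV satisfy

    Var(û_p) = Cov(û_w, û_p) = G − C22_p,
    Var(û_w) = G − C22_w,
    û_w | û_p ~ MVN(û_p, C22_p − C22_w),

with `G = A_vv σ²_g` and `C22` the prediction-error (co)variance blocks:
`σ²_e` times the animal block of the inverse MME coefficient matrix. These
identities are the engine's core contract; the test suite checks them both
algebraically (exactly, on a small system) and by replicated simulation
(elementwise within Monte-Carlo error). Everything downstream breaks if
selection operates on the data: the conditional distribution above then no
longer holds, intervals can be biased in location and length, and the
package makes no attempt to correct for it.

## Variance derivations implemented

* **Bias** `μ_wp = mean(û_p − û_w)`: `Var = 1′(C22_p − C22_w)1 / n²`. This is
  an exact Gaussian moment.
* **Dispersion** `b_wp = û_w′Sû_p / û_p′Sû_p`, `S = I − 11′/n`: by the law of
  total variance, the conditional-mean term is identically zero (the
  conditional expectation of the slope is 1 whatever `û_p`), and no such term
  is added anywhere. The remaining term is evaluated with a first-order
  Taylor approximation of the ratio, giving
  `tr(SDSP) / (2 tr(SPSP) + tr(SP)²)` with `D = C22_p − C22_w`,
  `P = G − C22_p`. **This is an approximation with relative error O(1/n)**:
  for isotropic inputs the exact value is `E[1/χ²_{n−1}] = 1/(n−3)` against
  the formula's `1/(n+1)`, i.e. almost a factor 2 at n = 8 but a few percent
  at the cohort sizes (n ≳ 50) validation is run at. The slope's sampling
  distribution is heavy-tailed for n ≤ 5 (its variance need not exist), so no
  finite-sample variance formula can behave there.
* **Reliability** `ρ²_cov = û_w′Sû_p / (n σ²_gi)`: numerator variance from
  exact Gaussian quadratic-form moments,
  `Var = [tr(SDSP) + 2 tr(SPSP)] / (n σ²_gi)²`. Exact, like the bias.
* **Ratio of accuracies / predictivity**: Fisher transform,
  `tanh(atanh ρ ± z/√(n−3))`; for predictivity the printed scaled form
  `(1/h)·tanh(h·atanh(ρ) ± z/√(n−3))` is used. The transform assumes iid
  samples, which focal cohorts are not; it is used because it behaves well
  in practice and exact alternatives are unusable. `atanh` requires
  `|ρ| < 1`; predictivity estimates can exceed 1 in magnitude at low h²
  (the raw correlation is divided by h), in which case the interval is
  reported as missing rather than fabricated.
* **Wald intervals** use `z_{1−α/2}` from the standard normal quantile
  (α default 0.05). Trace expressions can go marginally negative when the
  information gain is tiny (`C22_p ≈ C22_w`); variances are clamped at zero
  and flagged.

S-quadratic forms are computed by explicit mean-centering (for vectors) and
double-centering (for matrices); `S` is never materialised.

## Reliability-only approximations

When the `C22` blocks are unavailable, all off-diagonals of `G`, `C22_w`,
`C22_p` are assumed negligible, so `C22 = σ²_g (I − R)` with `R` the diagonal
reliability matrix. This yields

* bias: `Var ≈ (σ²_g/n)(mean rel_w − mean rel_p)`;
* dispersion: `Var ≈ Σ(rel_wi − rel_pi) rel_pi / (2 Σ rel_pi² + (Σ rel_pi)²)`,
  and with a constant ratio `rel_w/rel_p = c`:
  `(c−1)(V + m²) / (2(V + m²) + n m²)` with `m = mean(rel_p)` and `V` its
  **population** variance (divisor n — required for the per-animal and
  constant-c forms to agree exactly under homogeneous reliabilities);
* reliability: `Var ≈ (1+c) σ⁴_g (V + m²) / (n σ⁴_gi)`.

`c` is computed as `mean(rel_w)/mean(rel_p)` and floored at 1; the per-animal
form is the default whenever both reliability vectors are available. The
diagonal assumption is good for weakly related, highly reliable animals and
degrades for sibship-structured cohorts with low reliabilities.

## Validation-group genetic variance

The reliability estimator divides by `σ²_gi`, the genetic variance of the
focal group. The default is the relationship-average formula
`σ²_gi = σ²_g (mean(diag A_vv) − mean(A_vv))`, the expected variance of
breeding values around the group mean: it shrinks for closely related groups
and vanishes for clones. It is a modelling choice, not a theorem — the mode
used (`relationship_average` or `user_supplied`) is recorded in every result
and report, and a user-supplied value (e.g. a selection-corrected one) takes
precedence when given.

## Bootstrap

Focal individuals are resampled with replacement, keeping each individual's
`(û_p, û_w, y*)` tuple intact; the statistic is recomputed per resample.
Default interval type is percentile (2.5/97.5 empirical quantiles); a
normal-approximation variant is available. B defaults to 10,000; seed, B,
interval kind and the count of redrawn degenerate resamples are recorded.
Resampling treats the tuples as iid, which ignores the covariance structure
among focal animals — the simulation harness shows the resulting intervals
are systematically not wider (often narrower) than the analytical ones,
particularly for the dispersion at high phenotyping proportions.

## Williams test

To compare the predictivities of two prediction methods A and B evaluated
against the *same* adjusted phenotypes, the package implements Williams' t
for dependent correlations sharing a variable, with

    |R| = 1 − ρ²_A − ρ²_B − ρ²_AB + 2 ρ_A ρ_B ρ_AB

(the determinant of the 3×3 correlation matrix, i.e. squared correlations in
the linear terms — the standard Williams/Steiger form) and
`T ~ t(n−3)` approximately. The degenerate case ρ_A = ρ_B returns T = 0
exactly (including ρ_AB = ±1, two identical predictors); ρ_AB = ±1 with
ρ_A ≠ ρ_B is an error. Simulated type-I error at α = 0.05 is verified to lie
in [0.03, 0.07].

## BLUP engine numerics

* Dense assembly over **all** pedigree animals; `A⁻¹` by direct inversion of
  the tabular-method `A`. Intended scale is desk-size pedigrees (≤ ~10,000
  animals); no sparse machinery.
* One Cholesky factorization per dataset, cached; repeated phenotype
  replicates reuse it. Solves enforce a 1e−8 relative residual.
* `C22` focal blocks come from one unit-vector solve per focal animal —
  exact, never a full inverse, never a sparse approximation.
* Identifiability: the first fixed factor is coded cell-means (full dummy),
  further factors drop their first level. A singular system raises an error
  naming the factor levels in play.
* `y*` adjusts focal phenotypes with whole-data fixed-effect estimates by
  default (partial-data estimates are an option but fail loudly when the
  focal cohort's level is not estimable from partial data, e.g. when the
  whole last generation is truncated). The choice is recorded in metadata.
* `C22_p − C22_w` is checked positive semi-definite to 1e−8; reliabilities
  `1 − PEV_ii/(a_ii σ²_g)` are clipped to [0, 1].

## Simulation harness

The generator emulates a discrete-generation, random-mating, unselected
population: founders plus `matings × offspring_per_mating` animals per
generation, both parents drawn uniformly (distinct) from the previous
generation. Phenotype slots go to a uniform random `round(prop·N)` subset
(redrawn, with a warning, if a generation would be left without records),
with generation as the fixed effect and `b = 0` (fixed-effect values cancel
in BLUP under the correct model, so the zero default is immaterial).
Phenotypes are drawn per replicate as `y = Xb + Z L_A ξ √σ²_a + ε` with
`L_A` a Cholesky root of `A`, distributionally identical to
`MVN(Xb, ZAZ′σ²_a + Iσ²_e)`; `σ²_e = σ²_a (1/h² − 1)`. True breeding values
are retained per replicate so that accuracy-type targets can be checked
directly.

Per scenario (h², prop) the MME factorizations, `C22` blocks, reliabilities
and analytical/approximated variances are computed once — they do not depend
on `y` — and each replicate contributes the five statistics and per-method
intervals. The empirical ("true") reference per scenario is the replicate
distribution: its SD and its 2.5%/97.5% quantiles (linear-interpolation
quantiles). Coverage is the fraction of replicate CIs containing the target
(0 for bias, 1 for dispersion, the replicate mean for the correlation-type
statistics); mean-squared-difference tables compare each method's variance
and CI bounds against the empirical ones, pooled and grouped by h² or prop.

Default problem sizes are desk-scale, chosen so the full default grid runs in
minutes on one core: a ~600-animal pedigree (5 generations of ~120), grids
h² ∈ {0.1, 0.3, 0.6} × prop ∈ {0.3, 0.6, 0.9}, 500 replicates, harness
bootstrap B = 1000 (the standalone bootstrap default stays 10,000). The full
9×9 grid in steps of 0.1 with an external pedigree file and 50 replicates per
scenario is configured the same way (`pedigree_file`, wider grids) and simply
takes longer.

Reproducibility: every random stream derives from the master seed via
`SeedSequence` spawn keys — (0,) pedigree, (1, j) phenotype assignment for
the j-th prop, (2, s, r) phenotype draw for replicate r of scenario s,
(3, s, r) its bootstrap. Identical (config, seed) reproduce every table
bit-exactly.

What the generator does **not** emulate: selection (by construction),
overlapping generations, unknown-parent groups, heterogeneous residual
variances, genotypes or genomic relationships, and record-attrition
patterns of real recording schemes. Passing coverage here demonstrates the
formulas are correct under their stated assumptions — not that intervals are
well calibrated for selected populations.

## Known limitations

* The dispersion variance is a large-n approximation (see above); its Wald
  interval slightly under-covers at moderate cohort sizes (~94% observed at
  n ≈ 55 against a 95% nominal level).
* The Wald form is used for the reliability despite visible skewness of its
  sampling distribution in some settings; no transformation is applied.
* Fisher-type intervals ignore dependence among focal animals.
* No selection correction anywhere: `G − C22_p` overstates `Var(û_p)` under
  selection, with knock-on effects on the dispersion and reliability
  intervals.
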