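# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions that were genuinely open.

## Scope and data model

The package estimates realized genetic gain from ERA trials: common-garden
evaluations of varieties released across different years. An *environment*
(equivalently *trial*) is a site × year combination, labelled `SITE_YEAR`
throughout. Plot records carry trial, genotype, replicate, incomplete block
(nested in replicate), grain yield (t/ha), and the covariates
days-to-flowering (days) and plant height (cm). All yields are handled
internally in t/ha; kg/ha figures appear only in reports (slope × 1000).

## Stage 1 — per-trial mixed models

Model: `y = μ + rep + block(rep) + genotype + covariates + error`, with
replicates and blocks random and homoscedastic independent errors.
Covariates are centered at their trial means, so genotype BLUEs are
adjusted means at average covariate values; a covariate that is constant
within a trial (or entirely missing) is inestimable and dropped with a
warning. When every replicate contains a single block, the block term is
collapsed into the replicate term.

Variance components are REML estimates from a dense representation of the
marginal covariance `V = Σ σ²_k Z_k Z_kᵀ + σ²_e I`. Variances are
optimised on the log scale with a quasi-Newton method (L-BFGS-B) using the
analytic REML gradient `∂(−2ℓ_R)/∂θ = tr(P ∂V) − yᵀP ∂V P y`; convergence
is declared at a relative change in −2ℓ_R below 1e−8 with at most 200
iterations; components driven to zero are pinned at the lower bound of the
log grid (about 1e−10) rather than removed mid-optimisation. Trials here
have at most a few hundred plots, so dense Cholesky algebra is both exact
and fast; the engine is cross-checked in the tests against closed-form
balanced ANOVA estimators, statsmodels MixedLM, and an explicit
pseudo-inverse GLS oracle.

Heritability uses the two mean-basis estimators: Cullis
`H² = 1 − v̄Δ(BLUP)/(2σ²_g)` with `v̄Δ(BLUP)` the average variance of a
difference of two genotype BLUPs (from the PEV matrix of the
genotype-random fit), and Piepho `H² = σ²_g/(σ²_g + v̄Δ(BLUE)/2)` with
`v̄Δ(BLUE)` from the variance matrix of the genotype BLUEs. In a balanced
trial the two coincide (verified to 1e−8). Both are clamped to [0, 1];
`σ²_g = 0` returns (0, 0, 0) with a flag rather than an exception.
Reliability is the mean BLUP reliability `1 − PEV_k/σ²_g`; because the PEV
includes the uncertainty of the absorbed trial mean, it has a `1 − 1/m`
ceiling for `m` genotypes — harmless at trial sizes of 20+ but visible in
tiny examples.

Outlier screening: observations with |standardized marginal residual| above
a configurable threshold (default 4.0) are set missing, logged, and the
trial refit once. A large spike inflates the estimated residual variance
itself (masking), so thresholds near 3 are more sensitive on small trials.

Quality control retains trials with `H² > 0.1` **and** reliability
`r² > 0.15` (strict inequalities, Cullis H² by default); every exclusion is
logged with its values.

## Kinship

The numerator relationship matrix is built by the tabular method
(`a_ii = 1 + a(p₁,p₂)/2`, `a_ij = (a(j,p₁) + a(j,p₂))/2`), with unknown
parents treated as unique non-inbred founders; a parent id that never
appears as a record is treated the same way with a warning. Equivalence
with an independent coancestry recursion is tested on random pedigrees to
1e−12, along with positive semi-definiteness and the property that adding
individuals never changes existing entries.

"Sibship" counts are defined operationally as connected components of the
graph whose edges join pairs with `a_ij >` threshold (default 0, i.e. any
nonzero relatedness). This is an explicit proxy for the visual cluster
counts one reads off an NRM heatmap.

## Stage 2 — weighted factor-analytic G×E model

Stage-1 BLUEs are the response; trials are fixed effects; genotype main
effects have covariance `A σ²_g` (pedigree NRM) or `I σ²_g`; G×E effects
are independent across genotypes with environment-level covariance
`ΛΛᵀ + Ψ` (FA2: Λ is environments × 2, Ψ diagonal); residuals are
independent with variance `se²_ij σ²_θ` — the squared stage-1 standard
errors as known weights with one free multiplier (an unweighted variant is
available by flag). REML again on the dense marginal covariance with
analytic gradients; identifiability of Λ is imposed by fixing element
(1, 2) at zero during optimisation and flipping column signs so each
factor's first nonzero loading is positive. With fewer than four
environments FA2 degenerates and the model falls back to FA1 (logged).
If the pedigree-correlated fit fails, it refits with `A = I` and flags the
fallback.

**The aliasing ridge.** With `A = I`, the genotype main-effect variance
`σ²_g 11ᵀ` is exactly aliased with a constant loading column: the
restricted likelihood is flat along transfers between them, and where an
optimiser stops on that ridge is arbitrary. Two consequences are handled
explicitly:

* *Breeding values* are defined as the genotype prediction
  `g_i + (1/k) Σ_j (g×y)_ij` (main effect plus average interaction BLUP,
  plus the fixed-effect mean), which is invariant to where the ridge
  settles.
* *Genetic correlations between environments* are computed from the total
  genetic covariance `C = σ²_g + ΛΛᵀ + Ψ` — the identified quantity —
  rather than from the factor part alone. Environments with zero total
  genetic variance get undefined (NaN) entries rather than zeros.

Connectivity (the count of genotypes shared by each environment pair) is
reported; a disconnected genotype–environment incidence graph is an error
naming the components, since genetic correlations between disconnected
groups are inestimable.

## Finlay–Wilkinson stability

The environmental index `E_j` starts at the centered environment means of
the BLUE table (the classical choice; "environmental quality" has no other
operational definition here). On complete tables the per-genotype
regressions on this index are already the least-squares solution, so a
single pass is taken; with missing cells the index and the regressions are
alternated to joint convergence (max |Δb| < 1e−10), re-centering `E` and
rescaling so that mean(b) = 1 after each pass (the product `b_i E_j` is
invariant to this normalisation). `b_i` is the total slope on the index —
1 means average sensitivity. Genotypes observed in fewer than two
environments are excluded with a warning; a zero-variance index is an
error.

The ANOVA partitions the corrected total into Environment, Variety,
Regression (heterogeneity of the `b_i` around 1, `SS = Σ_i (b_i−1)² Σ_j E_j²`
over each genotype's observed environments) and Error, with df
`(k−1, m−1, m−1, N_obs − 1 − (k−1) − 2(m−1))`. On complete tables the four
sums of squares add to the corrected total exactly; with missing cells the
partition is the analogous sequential one. All three effect rows are
F-tested against the error mean square; zero error df yields undefined
F/p, not an exception. The ranking output sorts by mean performance
(ties broken by genotype id) and carries `b_i` so "high and stable" is
selectable.

## Genetic trend and percentage gain

Breeding values are regressed on release year by OLS (optionally weighted
by prediction SE). `β` (t/ha/yr) is the genetic trend; `a₁`/`aₙ` default to
the earliest/latest release years present. Percentage gains divide β by
the predicted baseline yield at `a₁` and at the midpoint `(a₁+aₙ)/2`; both
are invariant to unit rescaling and undefined (error) when the baseline is
non-positive. The β interval is a Wald t-interval; the gain ranges scale
the β endpoints by the baseline held at the point estimate — re-evaluating
the baseline at each endpoint is non-monotone in β (the derivative has the
sign of γ) and can produce ranges excluding the point estimate, so it is
not used. Because breeding values are shrunken predictions, β inherits
mild attenuation when reliabilities are low; at the emulated designs the
effect is small relative to the sampling sd (~10 kg/ha/yr at 24
genotypes), and the reported SEs are calibrated (checked by simulation).

## Synthetic data generator

The generator is the test bed: it produces datasets with exactly the
moment structure the models assume, plus the design features that make ERA
data awkward (partial connectivity, heterogeneous trial means).

* **Designs.** Three ecology presets: 36 genotypes × 8 trials (irrigated
  lowland), 24 × 6 (rainfed lowland), 20 × 4 (rainfed upland); release
  window 1986–2020; alpha lattices with 3 replications and block sizes
  6/6/5; per-trial mean yields set to the observed trial means of the
  corresponding networks (2.2–8.3 t/ha).
* **Genetic values.** `g_i = γ + β a_i + τ_i` with preset trend slopes
  β = 0.007/0.012/0.010 t/ha/yr, γ centered so the mean deviation is ~0,
  and `τ ~ N(0, 0.08)` t²/ha² — giving trend R² near 0.15, in line with the
  weak-signal regime such networks operate in.
* **G×E.** Per-genotype environment vectors from `N(0, ΛΛᵀ + Ψ)` with
  deterministic loadings (first factor 0.25–0.55 everywhere positive — a
  common performance axis; second factor alternating ±0.15–0.18 — a
  crossover axis) and `Ψ` in 0.01–0.15 t²/ha².
* **Plots.** `y = μ_env + rep + block(rep) + g + ge + covariates + error`
  with σ²_rep = 0.05, σ²_block = 0.03, σ²_error 0.35–0.55 by ecology.
  Implied per-trial heritability `H² ≈ σ²_G(j)/(σ²_G(j) + σ²_e/3)` with
  `σ²_G(j) = β²Var(a) + σ²_τ + λ_j² + ψ_j` lands roughly in 0.3–0.85,
  within the range such trials report. Covariates are genotype-level means
  plus plot noise with small yield slopes (+0.004 t/ha per cm height;
  ±0.002–0.01 t/ha per day to flowering, sign depending on ecology).
* **Connectivity.** Missingness removes whole genotype × environment cells
  (default rate 0.2), mirroring how ERA entries drop out of sites; every
  genotype is forced to remain in ≥ 2 environments and every environment
  keeps ≥ 2 genotypes.
* **Pedigrees.** Founders plus full-sib families from disjoint founder
  pairs; trial entries are the terminal individuals (non-parents). Preset
  family structures make the relatedness-cluster counts among entries come
  out at 32/22/14 for the three ecologies: with `f` families of total size
  `s` and the rest singleton founders, the entry set has
  `(n_genotypes − s) + f` clusters.
* **Truth.** Every draw (genetic values, τ, G×E matrix, release years,
  generating covariance) is recorded and serialized alongside the data.

What the generator does **not** emulate: spatial field trend within trials
(no row–column structure), weather-driven G×E (environment effects are
free means, not functions of covariates), genotype-specific error
variances, and non-normal yield contamination beyond what the outlier
screen is tested with. Passing tests therefore demonstrate correct
inference under the stated model class and design, not robustness to
field artefacts outside it.

## Problem sizes and determinism

Monte-Carlo checks use 10,000 genotypes for generator moments, 20
replicates of 50 × 6 tables for FA recovery, 200 replicates of the full
rainfed-lowland pipeline for trend recovery, and 1000 regressions for
interval coverage — sizes at which the binomial/Monte-Carlo noise is well
inside the asserted tolerances. All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); identical config + seed gives
byte-identical outputs, and the run report records the seed.

## Known limitations

* Stage-2 REML cost grows with the cube of the number of observed cells;
  the dense engine is meant for ERA-scale tables (tens of genotypes × ≤ 10
  environments), not for hundreds of environments.
* The σ²_g/Λ ridge means the *split* between main-effect and factor
  variance is not interpretable with an identity genotype covariance; only
  ridge-invariant summaries (breeding values, total genetic correlations)
  are reported as results.
* The FW ANOVA partition is exact only on complete tables; with missing
  cells it is a documented sequential approximation.
* Trend estimates from a single ~24-genotype network have sampling sds
  near 10 kg/ha/yr; single-run slopes should be read with their intervals,
  and negative point estimates at true slopes of ~10 kg/ha/yr are within
  normal sampling behaviour.
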