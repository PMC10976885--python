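# Methods

This note documents the statistical model behind `mtbvs`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## The multitrait variable-selection model

For n participants, q continuous traits `Y` and p candidate exposures `X`
(log10 concentrations), both residualized on the adjustment covariates and
standardized, the model indexed by the inclusion vector γ (k = |γ|) is

    Y = X_γ B_γ + E,   rows of E iid N(0, Σ)

with the conjugate prior

    B_γ | Σ ~ MatrixNormal(0, g (X_γᵀX_γ)⁻¹, Σ),   p(Σ) ∝ |Σ|^{-(q+1)/2}.

Integrating out B and Σ gives the marginal likelihood, up to a
γ-independent constant,

    log m(Y|γ) = −(qk/2) log(1+g) − ((n−1)/2) log det(YᵀY − c·YᵀP_γY),

where c = g/(1+g) and P_γ projects onto span(X_γ). The shrinkage scalar
defaults to g = n (unit-information). The (n−1) exponent reflects the
degree of freedom absorbed by the intercept during residualization.

Two consequences of this unit-information choice matter for interpreting
null behaviour:

* Adding a predictor carrying no signal costs ≈ (q/2)·log n in log marginal
  terms, so with q traits the Occam factor is multiplied q-fold. Under a
  global null the posterior therefore concentrates on the empty model and
  every MPPI sits at (or near) zero — it does *not* hover at the marginal
  prior inclusion probability E/p. The prior-tracking identities (null
  MPPI ≈ E/p; posterior size distribution ≈ truncated size prior) hold
  exactly only in the flat-likelihood limit g → 0, and that is how the
  corresponding tests are phrased.
* The same q-fold penalty is what gives the multitrait analysis its power:
  an exposure with a modest effect *shared* across traits accumulates
  evidence across all q columns while paying the entry cost only once.

### Covariate adjustment

All models are adjusted for age, gender, education, smoking and the diet
PCA scores by projecting both Y and X onto the orthogonal complement of the
covariate span and re-standardizing. Under the conjugate prior this is
equivalent to forcing the covariates into every model, up to
degrees-of-freedom corrections of order 1/n. A predictor whose residual
variance falls below 1e-10 after projection is rejected by name as
collinear with the adjustment set.

### Model-size prior

Model size k has a beta-binomial(p, a, b) prior with (a, b) solved from the
prior mean E = 5 and standard deviation S = 4 by moment matching, truncated
at T = min(p, E + F·S) with F = 7 and renormalized; each model of size k
gets the size mass divided by C(p, k). When S² is at or below the binomial
variance (matching infeasible) or beyond the maximal beta-binomial
dispersion for that p, the prior falls back to a pure binomial with a
logged warning — this happens by construction in small-p test fixtures
(e.g. p = 6 with S = 4).

With p = 33 the matched prior has mean 5.00 and sd 4.00 before truncation
(exactly, by construction) and P(k ≤ 14) = 0.972. Descriptions of this
prior family sometimes quote "99% of the mass below 14"; the faithful
moment-matched construction concentrates slightly more mass in the upper
tail (the matched beta parameters are a ≈ 1.60, b ≈ 8.95). The package
reports the computed coverage rather than adjusting the prior to meet a
quoted figure; the exact number is recomputed in the acceptance suite.

### The sampler

`run_guess` is an evolutionary stochastic search over γ with parallel
tempering:

* per sweep and chain, one mutation: add (prob 0.45), delete (0.45) or swap
  (0.10), Metropolis–Hastings-corrected for the asymmetric candidate counts
  and accepted at the chain's inverse temperature (the Hastings ratio is
  not tempered);
* with probability 0.33 per sweep, a uniform crossover between two random
  chains, accepted jointly at both temperatures;
* one exchange attempt per sweep between a random adjacent-temperature
  pair.

The temperature ladder is geometric (initial ratio 1.3) and adapted every
100 burn-in sweeps toward a 0.5 exchange acceptance rate, then frozen.
Proposals exceeding the truncation T or hitting a rank-deficient X_γ score
−∞ and are auto-rejected. Cold-chain states after burn-in are the visit
record; identical seeds give bitwise-identical logs. Marginal likelihoods
are computed from precomputed Gram matrices (O(k³ + k²q) per model,
independent of n) and cached per model, which is what keeps desk-scale
permutation studies cheap. Defaults are 30,000 sweeps, 10,000 burn-in,
3 chains; the test suite scales these down (typically 3,000–10,000 sweeps)
to keep runs in seconds while remaining well-mixed at p ≤ 33 — the
p = 6 oracle comparison shows TV ≈ 0.02 at full scale.

### Posterior summaries and decisions

MPP(model) = visits/(sweeps − burn-in); MPPI_j = Σ MPP over models
containing j (these identities are asserted exactly in tests). The MPPI
significance threshold t* is the smallest observed MPPI whose estimated
FDR — the mean number of permuted MPPIs at or above t across full sampler
reruns on jointly row-permuted outcomes, divided by the observed count at
or above t — is ≤ the target level (default 0.05, 20 permutations). If no
observed value qualifies, the significant set is empty and the threshold
reported is the sentinel ∞.

BF_j = [MPPI_j/(1−MPPI_j)] / [π₀/(1−π₀)] with π₀ = E/p, MPPI capped at
1 − 1/(recorded sweeps); RBF_j = BF_j / BF(t*), so RBF = 1 exactly on the
significance boundary and RBF ≥ 1 reads "at least as informative as a
boundary feature". When the threshold is the sentinel, the RBF reference
falls back to the maximum observed MPPI and the table is flagged; if even
that maximum is zero the RBF is undefined (NaN).

Effect sizes conditional on a model (typically the top best model visited)
are simulated from the conjugate posterior: per round, N_Σ = 2 draws of
Σ ~ InvWishart(n−1, YᵀY − c·YᵀP_γY), and per Σ draw N_B = 2 coefficient
matrices from the matching matrix normal centred at c·B̂; 500 rounds
(2,000 draws per coefficient) by default. A sign is called when the
25th–75th percentile interval excludes zero. Whether such simulation should
condition on the single top model or refresh per retained sweep is not
settled usage; conditioning on the top model is the default here and the
conditioning model is an explicit argument.

Known limitation of the permutation threshold: with few permutations and a
sharply concentrated null (all permuted MPPIs exactly 0), the threshold
collapses to the smallest nonzero observed MPPI, so features visited even a
handful of times become "significant". Under a global null with 20
permutations, the procedure's realized false-discovery proportion measures
0.00 (0/50 simulations) at the six-trait study scale — the multivariate
dimension penalty ties all null MPPIs at zero — but with weaker dimension
penalties (fewer traits) the rule inflates to ~0.1; increasing the
permutation count is the remedy the package exposes.

## Stability-calibrated networks

Conditional-independence networks are estimated by graphical LASSO
(L1-penalized Gaussian likelihood on the standardized data, scikit-learn
solver) on K = 100 subsamples of 50% of the participants. For a penalty λ
and selection-proportion threshold π, edges are classified as stably
selected (count ≥ ⌈Kπ⌉), stably excluded (≤ ⌊K(1−π)⌋, the symmetric rule)
or unstable. Under the instability null all edges are exchangeable with
counts ~ Binomial(K, μ̂), μ̂ the average selection proportion; the
stability score is the negative log-likelihood of the observed
classification under that null, maximized over a 20-point log-spaced λ grid
(from the empty-graph penalty down to 1% of it) and π ∈ {0.55, …, 1.00}.

Error control: the expected number of falsely selected edges is bounded by
q̂²/((2π−1)·N_edges) (q̂ = mean selected edges per subsample), the standard
stability-selection bound, and only (λ, π) pairs with bound ≤ PFER_max
(defaults 10 for the trait network, 20 for the exposure network) compete on
score. Ties prefer the sparser λ, then the stricter π. If no pair
satisfies the constraint the network is returned empty with a warning.

Multiblock mode (diet × chemical measurements) uses the same subsample
fits on a scalar λ grid but calibrates (λ, π) independently for each
block-pair edge set by that pair's own stability score, apportioning the
total PFER budget across pairs in proportion to their candidate edge
counts so the whole-network bound still holds. This trades the elegance of
a per-pair penalty matrix inside a single fit for a solver-free
construction with the same shared-subsample semantics.

Communities on the stable graph come from the Louvain method with unit
edge weights and resolution 1 (seeded); modularity is reported, with the
edgeless graph defined as singleton communities at modularity 0.

Trait selection for the multitrait outcome follows the network rule: keep
the traits with degree ≥ 2 in the calibrated trait network; if fewer than
two qualify the pipeline falls back to the full panel with a warning.

## Preprocessing

* **Exclusions**, in order: participants with no chemical measurement at
  all (a coded non-detect counts as a measurement), then participants
  missing ≥ 50% of the five diet items. Counts are logged and the
  conservation identity retained + Σ excluded = initial is enforced.
* **Below-LOD imputation**: per compound, a Gaussian is fitted on the
  natural concentration scale by censored-likelihood MLE (observed values
  above the LOD plus the censoring count; Nelder–Mead on (μ, log σ)), and
  flagged entries are replaced by truncated-normal draws on (0, LOD).
  With fewer than 10 quantified values the fit falls back to μ = LOD/2,
  σ = LOD/4 with a logged warning. Whether the original workflow fitted
  per-compound parameters or used fixed ones is not documented; both are
  supported (`params=` overrides the fit). The truncated-normal model is
  deliberately simple: on log-normal data with 30% censoring it restores
  the full-column mean to within 2%.
* **Missing data**: round-robin iterative conditional modelling
  (scikit-learn `IterativeImputer`, Bayesian-ridge learner per column,
  tolerance 1e-3, max 10 rounds) for numeric columns, mode fill for
  categoricals. A ridge learner extrapolates linear relations exactly,
  which tree ensembles cannot; the package does not attempt to replicate
  any particular random-forest imputer.
* **Diet PCA** on the z-scored five intake variables; the smallest number
  of components whose cumulative explained variance exceeds 95% is
  retained (3 on the default synthetic diet).
* Categorical covariates are one-hot encoded against reference levels
  never-smoker and low education.

## The synthetic cohort generator

The generator defines the study conditions the tests run under:

* **Exposures**: 33 compounds in the study's chemical families (3 PCBs,
  1 PBDE, 9 organochlorines, 9 organophosphates, 4 pyrethroids,
  2 phenylpyrazoles, 2 carbamates, 1 carboxamide, 1 dinitroaniline,
  1 oxadiazole), log10-normal via a Gaussian copula with latent
  correlation 0.5 within family and 0.1 between (a latent 0.5 implies a
  Spearman of ≈ 0.48 on concentrations, in line with the strongest
  reported within-family pairs). Per-compound LODs sit at the
  (1 − detection target) quantile of the generating distribution;
  detection defaults to a uniform 0.7 because the real per-compound
  detection table is not public, and a 10% detection floor is enforced.
  Technical missingness is MCAR at 2%.
* **Covariates**: age N(44.8, 13.5²), 69% female, education 39/23/38% and
  smoking 55/24/21% — the published cohort marginals.
* **Diet**: energy, proteins, fats, carbohydrates, fibres with published
  means/SDs and a three-factor correlation structure expressing that
  energy is nearly a linear function of the macronutrients; this pins
  corr(energy, fat) at 0.88 and makes three principal components carry
  >95% of the variance, as in the study. Intakes are floored at 1% of
  their mean to stay positive.
* **Traits**: nine cardiometabolic traits = sparse standardized exposure
  effects (on z-scored log10 concentrations) + covariate effects +
  Gaussian residuals with unit variances and a correlation matrix anchored
  at the published strong pairs (BMI–WC 0.89, TC–LDL-C 0.90, SBP–DBP 0.76,
  WC–FPG 0.51) and plausible moderate values elsewhere. Residual targets
  are specified as Pearson correlations; rank-correlation targets are
  treated as equivalent under the monotone transforms involved.
* The default cohort size is 941, the analysed sample size of the
  motivating study; cohorts with 439 panel-less and 48 diet-sparse extra
  participants reproduce the published exclusion flow from 1,428.

What it does **not** emulate: hair-growth kinetics or assay noise, real
detection-rate heterogeneity across compounds, informative missingness,
non-Gaussian trait margins, and any dependence of exposures on covariates
(exposure–confounder structure must be planted explicitly, as the
attenuation tests do). Passing tests therefore demonstrate correctness of
the machinery under a faithful but idealized correlation structure, not
performance on real hair-biomonitoring data.

## Numerical choices and degenerate inputs

* Positive definiteness of every generated correlation matrix is checked
  before sampling (smallest eigenvalue > 1e-10), with family blocks
  checked first so the error names the offending block.
* Marginal-likelihood Cholesky pivots below 1e-6 (relative) mark a model
  rank-deficient; inside the sampler that is an auto-reject, at the public
  API it raises.
* Stability scores clip category probabilities at 1e-300 before logging;
  an all-zero count vector is a valid (fully stably-excluded)
  classification.
* BMV ranking breaks MPP ties lexicographically on the predictor-name
  string so reports are deterministic.
* Graphical-lasso non-convergence on a half-sample triggers one retry with
  a 5% ridge blend; remaining near-convergence warnings are suppressed as
  irrelevant to support recovery.
* Empty cohorts, edgeless graphs, all-censored compounds and n = 0
  covariate tables all return well-defined degenerate outputs rather than
  raising.

## Scales used in the test suite

Oracle comparisons run at p = 6, q = 2, n = 50 with 30,000 sweeps;
parameter recovery at p = 33, q = 6, n = 500 with 10,000 sweeps and 10
replicates; null FDR calibration at p = 12, q = 6, n = 200 with 3,000
sweeps, 20 permutations and 50 simulations; network recovery at n = 941
with K = 100 subsamples (traits) and planted two-block designs at n = 400,
K = 50. These sizes were chosen so each study answers its question with
comfortable Monte-Carlo margins while the whole suite stays in the
ten-minute range on one CPU.
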