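# Methods

This note records the models, conventions and design choices behind
qsarlab, in enough detail to reproduce or audit any number the package
prints.

## Problem setting

A congeneric series of N-aryl dichloroacetamide-type cytotoxic compounds —
or any comparable small series — is modelled as a regression of activity
(pIC50, −log₁₀ IC50 in mol/L) on computed molecular descriptors.  The
characteristic regime is n ≈ 27 training compounds, a held-out external set
of ≈ 7, and hundreds of descriptors with strong block collinearity.  Four
model families are built and compared on identical data: stepwise MLR,
FA-MLR, PCRA and GA-PLS; the best model then drives applicability-domain
checked virtual screening.

## Descriptors

* **Graph conventions.** ATS/MATS/GATS and X3A are computed on the
  hydrogen-suppressed graph; H-048 needs explicit hydrogens; topological
  distance is the shortest-path bond count (disconnected pairs are infinite
  and excluded from every lag sum).
* **Pair conventions.** ATS sums over *unordered* pairs at the lag;
  MATS and GATS use *ordered* pairs with Δ = ordered-pair count:
  MATS = [Δ⁻¹ Σ (w_i−w̄)(w_j−w̄)] / [A⁻¹ Σ (w_i−w̄)²] and
  GATS = [(2Δ)⁻¹ Σ (w_i−w_j)²] / [(A−1)⁻¹ Σ (w_i−w̄)²] over retained atoms
  A.  These conventions are pinned down so the brute-force oracles in the
  test suite match exactly.  A lag with no contributing pair yields 0
  (logged), keeping descriptor matrices rectangular; constant weights raise
  a degenerate-descriptor error.
* **Atomic weights.** Carbon-scaled (w = p/p_C) atomic properties for
  H, C, N, O, F, S, Cl, Br, I: atomic mass; van der Waals volume from Bondi
  radii (4/3 π r³, e.g. C 20.58 Å³); polarizability (10⁻²⁴ cm³, e.g. C
  1.76); Sanderson electronegativity (e.g. C 2.746).  The table is a
  frozen dataclass and can be replaced wholesale by the caller.
* **X3A.** Mean over simple 3-bond paths of (δ_i δ_j δ_k δ_l)^(−1/2).  The
  averaging denominator (the simple-path count) is a convention of this
  package; descriptor software differs in this detail, so X3A values are
  comparable within qsarlab but not guaranteed to match other tools
  digit-for-digit.  ATS values are raw sums (no log transform).
* **Quantum indices.** Default convention follows the source study's
  printed formulas verbatim: η = 0.5(HOMO+LUMO), χ = −0.5(HOMO−LUMO),
  S = 1/η, ω = χ²/(2η).  Note these swap the roles the standard definitions
  give η and χ; `convention="standard"` selects η = 0.5(LUMO−HOMO),
  χ = −0.5(HOMO+LUMO).  η = 0 raises an error naming S and ω as undefined.
* **Fragment rules.** nROR: oxygen bonded to exactly two sp³ non-aromatic,
  non-carbonyl carbons.  nPhX: halogen on an aromatic carbon.  H-048:
  hydrogen on C2(sp³)/C1(sp²)/C0(sp) carbons, the digit counting carbon
  neighbours.  These verbal definitions admit edge cases; the rules above
  are the package's fixed reading.
* Externally computed descriptors (e.g. Dragon names like Ss, qpos, MAXDP,
  X3AV, ATS8p) are merged from a user table; provenance (native/external)
  is recorded per column.

## Model builders

* **OLS / stepwise MLR.** Incremental sum-of-squares partial-F tests;
  enter at p ≤ 0.05, remove at p ≥ 0.10 (the classic defaults), forward
  step then backward step until no move qualifies.  Ties in p are broken by
  larger |t| then lexicographic name, making reruns deterministic.
  Rank-deficient designs raise a collinearity error naming dependent
  columns.
* **Factor analysis.** Principal-component extraction from the correlation
  matrix of the (training-standardized) descriptors; the retained factor
  count is the smallest reaching the cumulative explained-variance target
  (default 95%).  Varimax rotation by pairwise Jacobi sweeps on
  Kaiser-normalized loadings, converged when the criterion gain < 1e-10;
  factor scores are unit-variance PC scores carried through the rotation
  and named FAC1, FAC2, …
* **FA-MLR.** Activity-relevant factors are found by stepwise selection on
  the factor scores; the candidate pool is every descriptor whose max
  |rotated loading| on those factors meets the threshold (default 0.6);
  stepwise MLR runs on that pool.  An empty pool raises a
  threshold-too-strict error.
* **PCRA.** Stepwise regression directly on the factor scores.  Retained
  predictors are orthogonal, so coefficients do not depend on the rest of
  the pool (tested).
* **PLS (NIPALS, PLS1).** X and y are standardized internally; with a
  single response each component is closed-form (w ∝ Xᵀy), and deflation
  gives nested sub-models.  The equivalent regression vector is
  b = W(PᵀW)⁻¹q, back-scaled to original units.  With the component count
  equal to the rank of X, PLS predictions equal OLS (tested at 1e-8).
* **Latent-variable count.** LOO PRESS for 1..max_lv (one NIPALS fit per
  fold, all counts from the nested model); chosen count = smallest k with
  PRESS(k)/min PRESS ≤ F(1−α; n, n), α = 0.25 — the Haaland–Thomas rule,
  favouring parsimony.
* **GA-PLS.** Binary chromosomes over descriptor columns; fitness is the
  LOO Q² of the per-chromosome PLS model with its own Haaland–Thomas
  component count; tournament selection (size 3), uniform crossover (rate
  0.8), per-bit mutation (rate 1/p), elitism 2, chromosome size repaired
  into [3, 15].  Defaults: population 64, 100 generations — the search
  hyperparameters are free choices of this package (they are not pinned
  down by the replicated study) and are logged in every `GAResult` together
  with the seed.  Fitness values are cached per subset, fitness ties within
  1e-6 prefer fewer descriptors, and a fixed seed reproduces the whole run
  bit-for-bit.

## Validation

* R² = 1 − SSres/SStot, SE = √(SSres/(n−k−1)), F = (SSreg/k)/(SSres/(n−k−1)).
* LOO: Q² = 1 − PRESS/SStot (SStot about the full training mean), RMScv =
  √(PRESS/n).  Default mode freezes descriptor selection and refits
  coefficients per fold, matching the usual workflow in which selection
  precedes validation; `strict=True` reruns the entire selection per fold
  (the unbiased variant).  Both modes exist because published workflows
  rarely state which was used.
* External set: R²p with the test-set mean in SStot; SEP = RMS prediction
  error.  Compound-ID overlap with training raises a leakage error.
* Y-randomization: activities permuted (default 100 times), the full
  selection+fit pipeline rerun per permutation; reports the permuted R²
  (or Q²) distribution and the original statistic's empirical percentile.
* A "Cvcv" statistic sometimes seen alongside these has no recoverable
  definition and is deliberately not implemented.

## Applicability domain

Leverage h_i = x_i(XᵀX)⁻¹x_iᵀ with the intercept-augmented,
training-standardized design restricted to the model's descriptors
(h is invariant to the affine standardization; candidates use the training
constants, so a candidate identical to a training compound inherits its
leverage).  Warning leverage h\* = 3(k+1)/n exactly.  Response outliers by
internally studentized residuals r/√(MSres(1−h)); the limit defaults to
3.0 SD with 2.5 SD as a conventional alternative, and the report header
states which is in force (both values are current practice; the replicated
workflow itself uses both in different places).  Flags are pure functions
of (h, residual, thresholds).

## Screening

Parents with IC50 < 9 µM (pIC50 conversion via 1 µM = 10⁻⁶ mol/L) seed the
enumeration; default rules replace an N bearing ≥1 H with O or S, dropping
the attached hydrogens (ester/thioester bioisosteres of amides).
Duplicate products are removed by a Weisfeiler-Lehman graph hash, so the
candidate set is independent of atom input order.  Candidates are predicted
by the chosen model, gated by the applicability module's flags verbatim,
and the in-domain candidates ranked by predicted pIC50; hits additionally
clear the activity floor (default pIC50 ≥ 5.25).  Candidate descriptors may
mix native computation and external columns.

## Synthetic data

The generator emulates the statistical shape of the target setting, not its
chemistry: descriptor marginals are standard normal; collinear blocks share
a latent factor (x = √ρ·z + √(1−ρ)·ε, giving within-block correlation ρ);
activity is a sparse linear function plus Gaussian noise.  The reference
condition (`study_spec`) uses 27 + 7 compounds, 200 descriptors (ten blocks
of 10 at ρ = 0.8 plus 100 independent), a 5-descriptor support with |β|
between 0.7 and 1.2, intercept 4.97 (the scale of the series' mean pIC50)
and noise 0.15 pIC50 units — the reproducibility scale of a careful
cytotoxicity assay on a log axis.  One root seed feeds separate substreams
for descriptors, noise and the train/test split.  Passing tests on this
generator demonstrate the *algorithms*; real descriptor data differ in
marginals, discreteness (fragment counts), and heavier collinearity, so
performance numbers on synthetic data do not transfer to real series.

## Numerical choices and scales

* Stepwise and GA tie-breaks are documented above; all RNG flows from
  explicit seeds; identical inputs reproduce identical outputs across runs.
* NIPALS stops a component early if the residual covariance norm falls
  below 1e-14; varimax converges at criterion gain < 1e-10; factor counts
  never exceed the numerical rank (eigenvalues > 1e-10).
* Studentized residuals of a numerically perfect fit (SSres ≤ 1e-20·SStot)
  are defined as 0; leverage exactly 1 raises an error naming the compound.
* Test-suite simulation sizes are chosen to exercise each property at
  desk scale: the GA recovery check runs population 64 for 60 generations
  on 10 seeds (measured 9/10 recovery of a 5-descriptor support among 100
  at noise 0.15); Y-randomization and permutation nulls use 100 draws.

## Known limitations

* Only the descriptor families used by the final models are computed
  natively; everything else must be supplied externally.
* X3A's averaging denominator and the ATS raw-sum choice are package
  conventions (see above), not certified reproductions of any specific
  descriptor software.
* The transcribed published equations are evaluable but their training
  statistics cannot be recomputed, because the underlying descriptor
  matrix was never published.
* No bootstrap validation, no regularized regression, no best-subset
  search, no distance-to-model AD variants, and no docking: screening ends
  at ranked in-domain predictions.
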