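# Methods

## The prediction problem

Each seawater sample carries a molecular fingerprint — intensities of
CHNOS molecular formulas resolved over retention-time segments from
LC-FTMS — and a scalar optical proxy for terrestrial dissolved organic
matter, the PARAFAC fluorescence component C475. The pipeline treats the
fingerprint as a feature vector and C475 as a regression target, and asks
which preprocessing and model family predict it best, and which features
carry the signal.

## Synthetic campaign generator

The generator produces data with the structure of the emulated field
campaign while keeping the ground truth known.

* **Formula space.** CHNOS compositions are drawn with carbon 6–40,
  oxygen binomial around 0.45·C, N ∈ {0,1,2}, S ∈ {0,1}; the hydrogen
  count follows from an integer double-bond-equivalent draw through
  H = 2 + 2C + N − 2·DBE, so every formula is chemically coherent, passes
  DBE−O ≤ 10, and has a neutral monoisotopic mass inside 150–1000 Da.
* **End members.** Two mean-intensity profiles over the formula space:
  the terrestrial profile up-weights masses near 300 Da and penalizes N/C
  and S/C exponentially; the marine profile up-weights masses near 650 Da
  and N/S-bearing formulas. A shared log-normal base intensity (σ = 1)
  models the heavy-tailed abundance distribution — the marginal intensity
  law is an artifact assumption, not an observed property.
* **Mixing.** Per sample, a latent terrestrial fraction τ ~ Beta(2, 2)
  mixes the profiles; a log-normal (σ = 0.25) per-sample scale models
  dilution. Elution spreads each formula over segments with a Gaussian
  peak (width 0.9 segments) plus a small baseline, normalized to sum to
  one.
* **Sparsity.** The time-aware table is thinned to the target zero
  fraction (default 0.793) by censoring the lowest intensities first — a
  detection-limit model; a uniform-random mode exists for property tests.
  Two sets of entries are never censored: a ubiquitous core (5% of
  formulas, present in every sample and segment, which keeps SUM/UBISUM/ALR
  well defined) and each feature column's maximum (so the realized column
  set, and hence the realized zero fraction, is exact).
* **Target and DOC.** C475 = c_min + (c_max − c_min)·τ + N(0, noise_sd),
  clipped at zero, with (c_min, c_max) = (0.00927, 0.0624); the default
  noise_sd = 0.002 is ~4% of the C475 range, comparable to fluorescence
  repeatability. DOC is affine in the post-thinning total sample intensity
  (default range 50–150 µmol/kg, typical open-ocean values) plus 2% noise,
  so DOC normalization is meaningful; the field campaign measured DOC, so
  this generative link is an artifact choice. Ten segments start at
  12.3 min in 1-min steps (the last segment ends at 22.3 min).

What the generator does **not** emulate: chromatographic peak shapes and
retention drift, isotopologues/adducts, seasonal or spatial structure, and
— most consequentially — multiple independent chemical drivers. One latent
factor (τ) generates every informative feature, so feature redundancy is
extreme: recursive feature elimination stays accurate down to a handful of
features, whereas field data degrade once the count falls below the number
of genuinely informative features. Passing tests therefore demonstrate
correctness of the machinery and recoverability of a known signal, not
field-scale difficulty.

## Wide tables

The time-agnostic entry for a (sample, formula) pair is the **mean over
the segments where the formula was detected**, not over all ten segments
with zeros. The defining sentence of the procedure scopes the mean to the
intensities "for that sample and formula" and describes zeros separately
as absences; the zero-inclusive reading would change every downstream
number. Records are sorted to a canonical order before aggregation, so
both builders are exactly permutation-invariant. Features are ordered
lexicographically by formula label, then segment, so regression weights
are byte-reproducible.

## Preprocessing conventions

* Pipeline order is build → eliminate → normalize; this order is required
  for the SUM ≡ UBISUM identity on ubiquitous tables, which the test suite
  asserts.
* A "spectrum" for SUM/UBISUM is the whole row for time-agnostic tables
  and each segment block for time-aware tables (each segment is one summed
  mass spectrum); UBISUM uses the same scoping with the denominator
  restricted to ubiquitous columns of that block.
* ALR uses the ubiquitous feature with minimal intensity variance (sample
  variance, ties broken lexicographically and logged) as the reference and
  replaces zeros by one-third of the **table-wide** minimum nonzero
  intensity. A single replacement constant keeps the transform monotone
  across samples; per-sample or per-feature minima would not. Natural
  logarithm; base changes are absorbed by regression weights.
* Target z-scoring uses the sample standard deviation (n − 1) and keeps
  (mean, sd) for an exact inverse. The z-score and the NRMSE range are
  computed on the **full dataset before splitting**, replicating the
  original protocol; this leaks only the target's location and scale, but
  a train-only mode can be obtained by passing the training slice.

## Modeling protocol

* **Split.** 80/20 stratified by target quantile (5 strata), train count
  rounded down (95 samples → 76/19), per-stratum allocation by largest
  remainder. CV folds are likewise target-stratified and re-randomized
  each repeat; the protocol default is 10-fold × 10 repeats.
* **Elastic net.** Zero intercept throughout (required for beta weights
  to read as terrestrial/marine directions). λ = 0 falls back to exact
  unpenalized least squares, α = 0 to an equivalent ridge solve; features
  are deliberately *not* rescaled between normalization and fitting,
  matching the benchmarked protocol — a caveat for lasso weight
  comparability that the interpretation stage inherits.
* **Random forest.** Variance split rule, mtry in sixths of the feature
  count, minimum node sizes {3, 5, 7, 10, 15}, 1000 trees by default;
  bootstrap structure is retained for OOB work.
* **SVR.** Polynomial kernel (x·x′ + 1)^d with scale fixed at 1, degrees
  1–5; RBF kernel exp(−σ‖x−x′‖²) with the σ ladder 1e-6, 2.5e-6, 6.25e-6,
  1e-5, 2e-5, 5e-5, 2.5e-4, 5e-4, 1e-3, 1e-2, 1e-1, 1 — the middle rungs
  of the ladder are ambiguous in the source description, so the realized
  grid is logged at run time. The ε-tube width is 0.1 on the z-scored
  target (the protocol never states it; 0.1 is the common library
  default) and is recorded in configs.
* **Grid search.** Score = mean RMSE over all validation folds; exact ties
  go to the stronger regularization (larger λ then larger α; smaller mtry
  with larger node size; smaller degree with smaller cost), making winners
  deterministic.
* **Significance.** Two-sided rank tests with continuity-corrected normal
  approximation (signed-rank for paired vectors, zero differences dropped;
  rank-sum otherwise). On tiny samples the approximation deviates from the
  exact sign-flip tail by up to ~0.01 in p; the test suite checks the
  approximation against exact enumeration at that tolerance.

## Importance and interpretation

* **SHAP.** Forests use the path-dependent polynomial-time tree algorithm,
  implemented in-package and verified against brute-force Shapley
  enumeration (the coalition value of a subset is the tree's expected
  prediction with absent-feature splits cover-averaged); additivity is
  exact. Other families use seeded permutation sampling, which is additive
  by telescoping at any draw count and converges to the Shapley value.
  Global SHAP rankings use mean |SHAP| over samples.
* **Permutation importance** shuffles feature values among each tree's
  out-of-bag samples and averages the OOB MSE increase over trees;
  features a tree never splits on contribute exactly zero.
* **Compositions.** Positive SHAP values of one sample are min-max scaled
  to [0, 1] over the positive subset (the stated scaling is ambiguous; a
  divide-by-max variant sits behind a flag) and used as weights on element
  counts; negative-SHAP features are read as marine and excluded. Weighted
  counts are convex combinations of the contributing formulas' counts.
* **RFE** drops ⌊0.1·p⌋ (≥ 1) least-important features per step, reports
  the 10-fold CV error of the omitted folds (not a held-out set), tunes
  hyperparameters once and re-derives only mtry as a constant fraction of
  the shrinking feature count.

## Problem sizes

The analysis drivers and the acceptance script run the full method at
desk scale: the default synthetic campaign (95 × 250 formulas), reduced
hyperparameter ladders (subsets of the full grids, which remain the
library defaults), 5–10 CV folds with 1–3 repeats, and forests of 30–150
trees. These sizes are the package's own choices for a reproducible
single-CPU analysis; all full-scale grids remain available through
`terradom.models.default_grid`.

## Known limitations

* The synthetic RFE curve does not reproduce the sharp error rise seen on
  field data below ~2000 features, for the single-latent-factor reason
  above; the RFE degradation property is instead verified on a
  multi-informative linear construction.
* Sampling SHAP is Monte-Carlo: per-feature values carry O(1/√draws)
  noise even though their sum is exact.
* The permutation-importance null check and seed-fraction assertions are
  statistical; they are run derandomized with fixed seeds.
* ALR's zero replacement and reference selection are computed on the full
  table (see the leakage note above).
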