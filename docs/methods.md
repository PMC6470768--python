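# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the open design choices of `milkomics`.

## Study design being modelled

The analysis targets a preterm mother-infant milk cohort: infants are
ranked by the change in weight Z-score between birth and hospital
discharge (SD units), and the top and bottom terciles define "faster"
(n = 11) and "slower" (n = 15) growth groups. Milk is sampled weekly at
lactation weeks 2–4; five to six LC-MS feature blocks (metabolome in
two ionisation modes, lipidome, glycome, free amino acids, total fatty
acids) are measured per milk sample, alongside pooled-QC technical
replicates. Twins share their mother's milk; in the emulated cohort two
twin sets are concordant (both slower) and two discordant (one infant
per growth group).

## Synthetic-data generator

`SyntheticConfig` defaults are the study conditions; they were fixed
from the design above, not adjusted to test outcomes.

- **Abundances.** Per feature, log-normal: log10 location ~ U(4, 7) and
  log10 scale σ ~ U(0.1, 0.5), matching the orders-of-magnitude spread
  of MS peak areas. Within-mother correlation is controlled by
  `week_corr` (default 0.5, the within-mother share of σ²; no published
  value exists, this is a generator parameter, not an assertion).
  A per-feature multiplicative week drift (log-slope ~ N(0, 0.05))
  provides a smooth lactation trend.
- **Group effects.** `n_planted` features per block receive a shift of
  ±`effect_size`·σ_j/2 per group on the log scale, applied at the
  *mother* level (milk belongs to the mother): a mother's shift is the
  mean of her infants' group signs, so mothers of discordant twins get
  zero shift and their milk is genuinely intermediate — exactly the
  behaviour reported for such twins.
- **Growth outcome.** ΔZ-score is a two-mode Gaussian mixture with
  modes −0.479 and −1.538 SD (the published group medians) and spreads
  0.28 / 0.54 SD (from the published quartiles). Birth weight is
  constructed to correlate with ΔZ-score at `birthweight_corr`
  (default −0.4, negative as observed).
- **Secretor biology.** Each mother is secretor with probability 0.8.
  2′-FL (feature `2100a`) and an LNFP-I analogue (`3110a`) are
  FUT2-dependent: non-secretor milk has these collapsed by 2.5 decades
  ("very low or no detectable" levels). Glycome features are named by
  HMO composition codes (Hex/Fuc/HexNAc/NeuAc counts plus isomer
  letter).
- **QC and missingness.** QC rows are log-normal technical replicates
  of the pooled mean profile with coefficient of variation `qc_cv`
  (default 0.15). Below-detection zeros are injected at `missing_rate`
  (default 0.02) into biological rows only — a pooled QC sample is by
  construction well above detection — and never into 2′-FL (the
  secretor call must remain defined).

What the generator does **not** emulate: batch effects and drift
between injections, retention-time shifts, correlated feature modules
(adducts/isotopes of one compound), heavy-tailed or missing-not-at-
random detection, and realistic annotation errors. Passing tests
therefore demonstrate that the statistical machinery recovers structure
it is designed for, not that real cohorts would give equally clean
results.

## Preprocessing

- **QC-RSD filter.** Features whose sd/mean over QC injections exceeds
  0.30 are removed. Features with zero QC mean are treated as unstable
  and removed.
- **Log-Pareto scaling** (metabolome, lipidome): x → log10(x + c), then
  per-feature centring and division by √sd. The pseudocount c defaults
  to half the block's smallest nonzero value (standard below-detection
  handling; no published value). Output variance per feature equals sd
  — an intermediate between centring and autoscaling appropriate for
  blocks with wide dynamic range.
- **Autoscaling** (glycome, FAA, FA): centring and division by sd.
  Constant features get scale 1 with a warning in either scaler; both
  scalers retain their statistics for projecting new samples
  (cross-validation refits use training-fold statistics) and for the
  inverse transform.
- **Relative HMO abundances**: percent of each sample's total HMO
  signal; rows sum to 100 exactly.
- **Weeks 2–4 are pooled** for scaling and the univariate tables (the
  published tables pool them); a per-mother-mean mode exists for
  sensitivity analyses.

## Secretor classification

Mothers are split by mean relative 2′-FL into two clusters at the
largest gap, computed on the log10 scale because the biological
contrast (secretor vs non-secretor) spans orders of magnitude while
within-cluster variation is fractional. A split is accepted only if the
gap is ≥ 3× the median of the remaining gaps **and** ≥ half the total
range; the second condition is needed because the largest tail gap of a
unimodal skewed sample routinely exceeds 3× the median gap, which would
otherwise mislabel low-2′-FL secretors. Independently of the
clustering, mothers below 1% relative 2′-FL are called non-secretor
(the absolute floor is the robust mechanism; the gap split serves
cohorts whose dichotomy sits above the floor).

## Latent-variable engines

- **PLS** is NIPALS PLS2 with X-deflation only (weights converge to
  Δw < 1e-12 or 500 iterations, then the best iterate with a warning).
  Y-loadings are regressions of the (undeflated) Y on each score;
  because scores are mutually orthogonal, per-component explained
  Y-variance SSY_a = ‖t_a‖²‖q_a‖² is additive. Sign convention: the
  largest-magnitude element of each X-loading is positive, making
  results platform-deterministic.
- **PLS-DA** fits PLS against the centred one-hot class matrix.
  Prediction is by nearest class centroid in score space with
  components weighted by √(SSY_a share): an unweighted rule lets
  noise-dominated trailing components flip calls even on well-separated
  data.
- **VIP** follows the standard definition; mean squared VIP is 1 by
  construction and is asserted on every fitted model in the test suite.
- **PCA** is SVD-based with the same sign convention; variance
  fractions are squared singular-value shares.
- **AoV-PLS** fits the PLS on (effect + residual), which in this
  single-factor design equals the centred matrix, so the one-way case
  reduces exactly to PLS-DA (asserted to score correlation ≥ 0.999);
  the explicit decomposition is kept so nuisance factors can be swept
  out before the PLS stage in extended designs.
- **Fisher LDA** on the leading A PLS score columns uses equal priors
  (the published plots show symmetric separation; configurable). A is
  chosen by minimising the sample-level LOO error of the full chain
  over A ∈ {1..5}; within `cv_error_chain` folds the full-data A is
  reused rather than re-selected (nested LOO would square the cost for
  a selection that is stable in practice). Singular within-class
  scatter gets a 1e-8 ridge with a warning.
- **MB-PLS** is fitted block-wise: per component the global weight
  vector is normalised across blocks, block scores are t_b = X_b w_b/ω_b
  with ω_b the block's weight norm (Σω² = 1), the super score is
  t = Σ ω_b t_b, and all blocks are deflated on the super score. This
  variant coincides with ordinary PLS on the weighted concatenated
  matrix — verified against that independent route in the tests — and
  ω² is the block importance (sums to 1 per component). Components are
  oriented so the "faster" class's mean super score is positive, which
  fixes the sign of the loading-based direction labels.

## Cross-validation and the twin problem

Leave-one-out is the study's validation currency. Two units of counting
exist because twins share one milk sample:

- The **AoV-PLS/LDA chain** reports the sample-level LOO error over
  infant-week observations (the published procedure), plus a dyad-level
  error obtained by majority vote over each infant's weekly folds.
- The **fusion LOO** is leave-one-mother-out: all rows sharing a milk
  sample are held out together. Plain per-row LOO is structurally
  invalid here — the held-out twin's identical milk row remains in
  training with its co-twin's label, so discordant twins would be
  misclassified deterministically rather than at the ~chance rate their
  intermediate milk warrants.

## Biomarker regressions

The response is one ΔZ-score per infant; milk features are collapsed to
the mother's mean over weeks 2–4 and duplicated to twins (a week-3-only
mode is available; the collapse rule is not published, so it is
explicit and configurable). All nine confounders enter every model
(with 26 infants this leaves ~15 residual degrees of freedom; a reduced
set is configurable). Missing confounders are handled by listwise
deletion, or by group-median imputation only when deletion would drop
more than 20% of infants (logged).

## Pipeline defaults

α = 0.05, MW q < 0.05, MLR q < 0.1 (reliable flag "#"), VIP ≥ 1.5,
QC RSD ≤ 0.30, 5 PLS components fitted / 2 displayed, fusion at week 3
with 2 common components and 1/√p_b block weights (no block dominates
by width; weight 1 is available). Tier glyphs in result tables:
q < 0.01 "**", q < 0.05 "*", q < 0.1 "t".

## Problem sizes in tests and the acceptance script

Simulation-based checks use the cohort's own dimensions where the check
is about the cohort (n = 11 vs 15 for type-I error; 26 infants for the
regressions and fusion) and compact fixtures (8×4 to 20×50) for the
algebraic oracles; stochastic checks average 10–20 fixed seeds. These
sizes are the package's chosen trade-off between the precision of a
Monte-Carlo assertion and keeping the default suite quick to run.

## Known limitations

- Two-class designs only (the study is two-group); no multi-class LDA.
- No mixed-effects modelling of the repeated weeks; the MLR stage
  reproduces the published plain-OLS analysis.
- No O-PLS, kernel PLS, or consensus-PCA/JIVE alternatives; only the
  UPCA and MB-PLS strategies of the workflow.
- The published R2Y figures from the original cohort are properties of
  unreleased data; the package reports its own R2X/R2Y for whatever
  data it is given and makes no claim to reproduce those numbers, nor
  the published selected-feature counts (125/119/68/87), which depend
  on the real feature correlation structure.
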