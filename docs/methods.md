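# Methods

## Model and procedure

The corrector assumes batch noise is additive on the log scale and
constant within a processing batch: for sample i (treatment α, batch j)
and feature g,

    x_gij = baseline_g + T_{α,g} + B_{j,g} + ε_gij.

Because principal component scores are linear in the features, the
shared term B_{j,g} surfaces on each component as an offset of batch
j's mean score; all batch-attributable variance lives in the batch
means, and all biological within-batch structure lives in the
residuals r_ji = s_ji − BM_j.  Correction therefore operates purely on
batch means, one component at a time:

1. **Decomposition.** SVD of the feature-centred N×p matrix (samples as
   rows).  Components with singular value ≤ 1e-10 of the largest are
   dropped; at most N − 1 remain.  Only centring is applied — variance
   scaling would distort the additive offset model.  Loadings are
   sign-fixed (largest-magnitude entry positive) so runs are
   reproducible; the correction itself is provably sign-invariant since
   it depends on |BM| only.
2. **Null model.** For each component and each batch composition
   {k_α}, the population of candidate-batch means over all
   ∏ C(n_α, k_α) ways of drawing k_α of the n_α replicates per
   treatment.  Its standard deviation is obtained by exhaustive
   enumeration when the candidate count is ≤ 1e5 (convolving
   per-treatment subset sums, so cost ~ candidate count), and otherwise
   by the algebraically identical finite-population formula
   Var = (1/m²) Σ_α k_α σ²_α (n_α − k_α)/(n_α − 1),
   with σ²_α the population variance of treatment α's scores (a
   treatment with a single replicate contributes nothing).  A
   Monte-Carlo route exists as a cross-check; equality of the exact and
   analytic routes is property-tested, not assumed.  Each batch gets a
   null from its own composition, so unequal batches are handled.
3. **Detection.** z_b = Φ(−|BM_b|/σ_b); the normalized likelihood
   L = (2^(b−1)/b) Σ_i Π_{j≠i} z_j combines them (leave-one-out
   products because centred batch means are linearly dependent — the
   last is fixed by the rest; the constant normalises L to 1 at
   all-zero batch means for any b).  1 − L is the confidence of a
   batch effect.
4. **Shrinkage.** If the confidence exceeds the limit, find the largest
   k ∈ [0,1] with confidence(k·BM) ≤ limit by bisection to |Δk| ≤ 1e-4
   (confidence is monotone in k; the plain fixed-step grid walk is kept
   as a test oracle).  Null standard deviations are computed once from
   the uncorrected scores and held fixed during the search: the
   candidate population embodies the no-effect hypothesis, compression
   is a hypothetical applied to the means.  Corrected scores
   k·BM_j + r_ji are assembled for all components and mapped back via
   scores·loadingsᵀ + feature means.  Components left at k = 1 keep
   their scores bit-identical; degenerate components (zero null spread)
   are never corrected.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `limit` | 0.95 | confidence limit: the trade-off coefficient between noise rejection (low values) and signal preservation (high values); correction stops where the confidence of a *remaining* effect would fall below it |
| `tolerance` | 1e-4 | absolute bisection tolerance on k; k is reported rounded to 2 decimals but applied at full precision |
| `null_method` | auto | exact enumeration up to 1e5 candidates, analytic beyond |
| `n_permutations` | 1000 | gPCA label permutations; p-values use the add-one estimator so they are never exactly 0 |

## Evaluation metrics

**Guided PCA.**  delta = var(X·v_guided) / var(X·v_unguided), where
v_unguided is the first right singular vector of the feature-centred
data X and v_guided that of YᵀX with Y the batch indicator.  The
statistic is implemented from this definition and validated by its
behaviour (null uniformity of the permutation p-value, power on strong
offsets, invariance to label renaming), not against any external code.

**Variance partition.**  Per feature, centred sums of squares are split
batch-first (batch means, then treatment means of the batch-removed
data, then residual), each divided by N − 1 and averaged over features.
Batch-first attribution deliberately assigns all batch-attributable
variance to batch; on balanced designs the order is immaterial (tested).
Designs where every treatment sits wholly inside one batch are flagged
confounded rather than rejected.

**Preserved variance** is the corrected-to-raw ratio of total
feature-centred variance (sum over features of the per-feature
population variance), clipped to [0, 1].  Other definitions of a
"preserved variance" axis are conceivable; this one is the package's
documented choice.

## Synthetic studies

The generator draws baseline_g ~ N(7, 1) (log2-intensity scale),
treatment effects N(0, treatment_sd²) with treatment_sd = 0.2,
batch offsets N(0, batch_sd²) with batch_sd = 0.3 constant per
(batch, feature), and i.i.d. noise N(0, noise_sd²) with
noise_sd = 0.1 — a batch effect three times the replicate noise,
dominant but not overwhelming, on a balanced 7-treatment ×
4-replicate / 4-batch layout (16384 candidate batches per composition).
`affected_fraction` restricts offsets to a subset of features, and
`batch_rank` draws offsets from a low-rank factor model to mimic the
spatially structured character of real batch distortion (default off:
full-rank offsets are the minimal model the corrector assumes).  All
randomness flows from one seed through named substreams (baseline,
treatment, batch, noise, affected) so components vary independently.

What it does *not* emulate: probe-level array geometry, intensity-
dependent (multiplicative) noise — log transformation is assumed to
have rendered noise additive — correlation between treatment effects
and batch offsets, and outlier samples.  Passing tests on this
generator therefore show the algebra and the detection/shrinkage logic
are right under the additive model, not that any particular real
dataset is corrected well.

Default feature counts in tests are 150–500 (2000 in the README
example) — far below real arrays, but the method's behaviour depends on
features only through the CLT smoothing of scores, which is already
saturated at a few hundred features.

## Numerical choices

- Rank cutoff 1e-10 (relative) on singular values; the number of
  retained components defines m.
- z floored at 1e-300 before products, and L itself floored at 1e-300,
  since a product of b − 1 floored values can still underflow;
  confidences are capped at 1 − 1e-15.
- k = 1 is the no-correction sentinel; the search may return values
  arbitrarily close to but below 1.  Reported k is rounded half-up to
  2 decimals.
- With unequal batch sizes, unweighted batch means are combined by the
  same likelihood rule, each against its own composition-specific null;
  only the size-weighted mean of batch means is exactly zero.

## Design choices and limitations

- **1 − L is a confidence score, not a calibrated p-value.**  For two
  equal batches L = z₁ + z₂ is exactly uniform under the null, but for
  b > 2 the likelihood concentrates near zero (E[L] = 2^(1−b) under
  independent uniforms), so on null data more than 5% of components
  show confidence > 0.95 — about 35% on the default 4-batch design.
  Consequently a conservative limit still touches a minority of null
  components; the touch is slight (the corrected matrix changes by a
  few percent under the null) because shrinkage stops at the detection
  edge.  Users who need strict type-I control should rely on the
  permutation-based gPCA test for detection and treat the confidence
  limit purely as a trade-off dial.
- **Shrinkage stops at the detection edge.**  At limit 0.95 the batch
  means retained after correction sit where a batch effect is still 95%
  credible, so a strong effect is reduced but not annihilated (k ≈ 0.4
  on the balanced default design regardless of effect size).  Driving
  batch-attributable variance to near zero requires a permissive limit
  (e.g. 0.10), which is also the setting under which the variance
  partition shows batch variance falling by >3 orders of magnitude with
  treatment variance untouched.
- The null is built from the observed scores, so a very large batch
  effect inflates its own null spread; detection confidence saturates
  rather than growing without bound.
- Within-batch geometry preservation is exact by construction
  (correction adds a constant per batch and feature), which also makes
  the treatment and residual components of the variance partition
  exactly invariant under correction on any design.
- Only batch + treatment designs are supported: no continuous
  covariates, no reference-batch or empirical-Bayes location/scale
  adjustment.
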