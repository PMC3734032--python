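# Methods

This note documents the statistical model implemented by `cvabms`, the
choices that were genuinely open when writing it, and what the synthetic
benchmarks do and do not establish.

## Source projection (LCMV beamformer)

Sensor-level complex Fourier coefficients are projected to a source
location with the linearly constrained minimum-variance filter
`w = C⁻¹l (lᵀC⁻¹l)⁻¹`, where `l` is the oriented lead field and `C` the
sensor covariance.  For free-orientation lead fields `L` (channels × 3)
the orientation `u` maximises projected power, which for unit-gain
weights equals `1/(uᵀLᵀC⁻¹Lu)`; the optimum is the eigenvector of
`LᵀC⁻¹L` with the smallest eigenvalue.  Choices:

* **No regularisation by default.**  The filter uses the plain inverse of
  `C`.  Rather than silently ridging an ill-conditioned covariance, the
  module raises once the condition number exceeds 1e12; callers may pass
  an explicit `ridge` (added to the diagonal, same units as `C`).
* **Numerics.**  All inversions go through a Cholesky solve, never an
  explicit inverse; the contract (unit gain `wᵀl = 1` to 1e-8) is what is
  tested, not the factorisation.
* **Sign and degeneracy.**  The power criterion does not identify the
  orientation sign; the first nonzero component of `u` is made positive
  for reproducibility.  A rank-deficient `L` leaves a null direction with
  unbounded power and no identified orientation, and is rejected.
* **Covariance window.**  Which trials enter `C` is the caller's choice;
  the simulated scenes estimate it from all trials of both conditions.

## Spectral features

A feature-set "model" of dimension d fractionates 3–90 Hz into d bands;
the built-in tables are

| d | bands (Hz) |
|---|---|
| 1 | 3–90 |
| 3 | 3–10, 10–30, 30–90 |
| 5 | 3–8, 8–12, 12–30, 30–50, 50–90 |
| 7 | 3–5, 5–8, 8–12, 12–20, 20–30, 30–50, 50–90 |
| 9 | 3–5, 5–8, 8–10, 10–12, 12–20, 20–30, 30–40, 40–50, 50–90 |
| 11 | 3–5, 5–8, 8–10, 10–12, 12–20, 20–30, 30–40, 40–50, 50–60, 60–70, 70–90 |

The trial feature is the mean of `s·conj(s)` over the bins of each band.
Band membership is half-open `[low, high)` with the top edge of the
final band closed: shared edges (10 Hz appears in both "3–10" and
"10–30") need a tie rule, and assigning the edge upward keeps every bin
in exactly one band.  Before model fitting each band is mean-removed
(pooled across both conditions) and scaled to unit variance so that
high- and low-power bands weigh equally.  The **population variance**
(divide by n) convention is used throughout, consistent with the
maximum-likelihood covariances in the evidence approximation.
Normalization statistics are computed per subject and per voxel — the
most local reading; nothing is pooled across voxels or subjects.

## CVA scoring and the BIC Bayes factor

Canonical correlations are the singular values of the whitened
cross-covariance `S_xx^{-1/2} S_xy S_yy^{-1/2}` of the centered design
and feature matrices; canonical vectors are back-transformed singular
vectors scaled to unit-variance variates.  Wilk's Lambda is computed
three equivalent ways (correlations; generalized eigenvalues of the
explained-vs-residual covariance split, via ρᵢ² = λᵢ/(1+λᵢ); and the
exponentiated likelihood ratio), and the test suite requires agreement
to 1e-10 — this cross-check guards the implementation.

The log evidence of the order-m model relative to the null is
approximated by BIC:

```
logBF_m0 = −(n/2) Σ_{i≤m} log(1−ρᵢ²) − (k_m/2) log n
```

* **Parameter count.**  `k_m = m(d + q − m)`, the parameter increment of
  a rank-m linear dependence over the null.  For the package's central
  use case (q = 1 condition label, single canonical vector) this gives
  `k = d`: model complexity grows one-for-one with the number of bands.
  The count is configurable (`param_count` argument) for users who
  prefer a different bookkeeping.
* **Degenerate inputs.**  Correlations numerically at 1 are clipped to
  1 − 1e-12 before logarithms and the result flagged `saturated`
  (exactly 1 yields +inf).  Feature covariances with eigenvalues below
  1e-10 × trace are floored with a warning naming the offending
  voxel/feature set.  Fits require n > d + q trials.
* **Order selection** is the argmax of logBF over m = 0…s, ties broken
  toward the smaller order (parsimony).

Because all models are scored against the same null on the same trials,
feature sets of different dimension are compared by differencing their
logBFs; the pairwise matrix is antisymmetric and transitive by
construction.

## Random-effects model selection

The subjects × models table of logBFs (null column ≡ 0) feeds the
Dirichlet fixed point

```
u_nk ∝ exp(logEv_nk + ψ(α_k) − ψ(Σ_j α_j)),   α_k = α0_k + Σ_n u_nk
```

with rows of `u` normalized through a log-sum-exp shift (evidence spans
hundreds of log units across voxels).  Choices:

* **Prior** α₀ = 1 per model: one previously observed instance of each
  model, a flat prior over frequencies.
* **Stopping rule.**  The update itself comes with no stopping rule;
  iteration ends when max|Δα| < 1e-6 or at 10,000 iterations, in which
  case the result is returned with `converged=False` and a warning.
* **Exceedance.**  For two models φ₁ = P(r₁ > ½) is the regularized
  incomplete Beta tail, computed exactly; for K > 2 it is a seeded
  Monte-Carlo argmax frequency (default 10⁶ samples for the standalone
  operation; the voxelwise map loop defaults to 10⁴ per voxel, which is
  accurate to ~0.005 and keeps whole-brain runs cheap).  A `method`
  switch can force the sampler, which is how the tests validate it
  against the analytic tail.
* **Degenerate input.**  An empty table returns the prior.

Note a structural ceiling that matters when reading maps: with N
subjects and K models the expected frequency of any model is at most
(α₀ + N)/(K·α₀ + N).  For N = 10 and K = 7 this is ≈ 0.65, so
"frequency > 0.9" summaries are only informative in pairwise (K = 2)
comparisons — the multi-way analysis is summarised by winner maps and
mean frequencies instead.

## Group maps

Subject scoring produces one record per subject × voxel × model; group
maps fit RFX-BMS independently per voxel.  Voxels lacking records for
any subject are excluded (with a logged count) rather than imputed.
Winner maps take the argmax expected frequency with ties broken toward
the lower model index, null first — parsimony again.  Maps are written
as NIfTI-1 volumes (`*_xpm` expected frequency, `*_epm` exceedance) when
voxel ids match a regular grid, with a CSV fallback.  No spatial
multiple-comparisons treatment is applied to thresholded summaries; the
counts are descriptive.

## Synthetic data: what it emulates and what it does not

`simulate_group_spectra` emulates per-trial Fourier coefficients of
1-second pre- and post-stimulus epochs on a 1 Hz grid from 3–90 Hz:
circularly-symmetric complex Gaussian noise per bin (flat baseline
spectrum; an optional 1/f weighting is available), with post-stimulus
power at effect voxels multiplied by (1 + effect) in specified bands.
Defaults — 10 subjects, 100 trials per condition, 100 voxels, 30 effect
voxels — represent a modest MEG group study.  The default effect
pattern (+0.50, −0.25, +0.05) on the three classical bands was chosen so
that the *weighted* broadband power change is near zero (7·0.5 −
20·0.25 + 61·0.05 ≈ +1.5 bins-worth over 88 bins): a low-frequency
increase offset by a mid-band decrease, with a small high-band rise.
This mimics the common post-stimulus pattern of theta enhancement with
alpha/beta desynchronisation and makes the benchmark a genuine
*feature-set selection* problem — the broadband scalar model gains
almost nothing, the three-band model captures the full pattern, and
finer fractionations capture the same pattern at a higher parameter
cost.  Between-subject variability scales each subject's effect sizes
by a lognormal factor (σ = 0.2).

What the generator does **not** emulate: realistic head geometry or
sensor covariance structure, temporally correlated or non-Gaussian
noise, phase effects, trial-to-trial amplitude drift, or spatial
correlation between voxels.  Passing the recovery benchmarks therefore
shows that the inference machinery is correct and well calibrated under
its own generative assumptions — not that real MEG effects of any
particular size will be detected.

`simulate_evidence_table` draws each subject's generating model from
known frequencies r and gives the assigned model a fixed logBF
(default 5, optional Gaussian dispersion), the direct analogue of the
random-effects generative model; it is used for frequency-recovery
benchmarks.  `simulate_sensor_subject` builds a one-source sensor-level
scene with a random free-orientation lead field so the beamformer path
is exercised end to end.

## Problem sizes in the benchmarks

The test suite and `scripts/acceptance.py` use: 50 random CCA instances
(n = 200, q ≤ 3, d ≤ 8) against an alternating-least-squares
maximization oracle; 100 random instances for the three-route Wilk's
Lambda identity; 500 null replicates (n = 200, d = 3) for calibration;
200 rank-1 replicates (n = 500) for order recovery; 100 evidence-table
replicates (N = 40) for frequency recovery; 20 Beta-tail comparisons at
10⁵ Monte-Carlo samples; 50 beamformer instances plus 10 sphere-grid
searches at 10⁴ orientations; and 10 seeded end-to-end group runs at
the default generator conditions.  These sizes make the whole
verification run in a few minutes on one core while keeping every
statistical check comfortably away from its decision boundary.

## Known limitations

* The BIC evidence is an asymptotic approximation; at very small trial
  counts it favours the null more than an exact evidence would.
* The parameter count for m > 1, q > 1 models follows the rank-increment
  convention above; other conventions shift all logBFs by an
  order-dependent constant and can change order selection near ties.
* Whether near-unit correlations should be clipped or treated as model
  failure is a judgement call; the package clips and flags.
* The RFX-BMS posterior is itself a variational approximation; its
  known optimism for small N is inherited, not corrected.
* Family-level inference and the Bayesian omnibus risk are out of scope.
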