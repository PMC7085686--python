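# Methods

## Model

An activity instance is a binary vector `x ∈ {0,1}^d` (one bit per home
sensor) with an activity label in `{1..p}`.  Classification runs in two
frozen stages.

**Stage 1 — stochastic-sensitive autoencoder.**  A single-hidden-layer
sigmoid autoencoder, code `c = σ(xW + b₁) ∈ (0,1)^h`, reconstruction
`y = σ(cV + b₂) ∈ (0,1)^d`, is trained by gradient descent on

    L(W, b₁, V, b₂) = R + w·STSM

with `R` the mean squared reconstruction error `(1/N) Σᵢ ‖y⁽ⁱ⁾ − x⁽ⁱ⁾‖²`
and STSM the *stochastic sensitivity measure*: the expected squared change
of the reconstruction map `g : x ↦ y` when the input moves anywhere inside
the Q-neighborhood `[x−Q, x+Q]^d`.  The expectation is approximated by
quasi-Monte Carlo:

    STSM ≈ (1/(N·J)) Σᵢ Σⱼ ‖g(x⁽ⁱ⁾) − g(x⁽ⁱ⁾ + Δxⱼ)‖²,
    Δxⱼ = 2Q·hⱼ − Q,

where `h₁..h_J` are the first J points (index 1 onward, unscrambled) of
the d-dimensional Halton sequence.  Gradients flow through both the clean
and every perturbed forward pass, so the sensitivity term shapes the
encoder itself.  Minimizing `R + STSM` minimizes the data-dependent part
of an upper bound on the *localized generalization error* — the expected
reconstruction error over the union of Q-neighborhoods of the training
points.  The bound itself,
`(√R + √STSM + √A)² + B·√(ln η / (−2N))` with worst-case constants A
(maximum output difference) and B (maximum possible MSE) and confidence
1−η, is exposed for reporting only (`lge_bound`) and never optimized; the
printed sources for this inequality are typographically ambiguous, so the
square-root composition above is implemented as stated and flagged here
rather than treated as ground truth.

**Stage 2 — RBF classifier on the frozen codes.**  The encoder is frozen;
its training codes are clustered by k-means into r centers `u_k`, each
with width `σ_k` = RMS distance of the cluster's members to its center.
Unit k responds with `φ_k(c) = exp(−‖c − u_k‖²/(2σ_k²))`, and a linear
output layer with bias maps activations to one-hot activity targets by
ridge least squares; prediction is the argmax of the scores, ties to the
lowest class id.  The unit count is selected greedily: one full network is
trained for every `r ∈ {p, p+step, …, ⌊N/2⌋}` and the minimum-training-MSE
network is kept (ties to smaller r).

## Parameters

| parameter | default | units / range | why |
|---|---|---|---|
| hidden width h | 20 | units | best width on most published binary-sensor corpora; corpora with sparse sensor coverage need more — hence the sweep command |
| Q | 0.1 | feature units | a small perturbation relative to the 0/1 gap of binary features; no published value exists, so this is the package's choice |
| J | 50 | Halton points | the estimator's published sample size |
| w (`stsm_weight`) | 1 | — | the objective is the plain sum R + STSM; the knob exists only for ablation (w = 0 is a plain autoencoder) |
| learning rate / epochs | 0.05 / 500 | — | full-batch descent; "backpropagation" is all the method prescribes, so a fixed-rate schedule long enough to converge on few-hundred-instance corpora was chosen |
| init scale | 1/√d | — | seeded uniform `[−s, s]` init |
| ridge | 1e−8 | — | keeps the output-layer normal equations well posed without visibly biasing the fit |
| r grid | p … ⌊N/2⌋, step 1 | units | the greedy search's published range; `step` exists for coarse sweeps |
| CV | k=10, 5 repeats | — | the standard repeated-CV protocol; stratified by default since activity supports are heavily skewed |

## Numerical choices

- Sigmoid is evaluated in the overflow-safe two-branch form; it saturates
  rather than diverges, so training with any finite learning rate stays
  finite — the divergence guard fires only on genuine parameter overflow
  and names the epoch.
- The STSM estimator as usually printed omits the 1/J factor; the
  implementation divides by N·J so the quantity is an expectation
  estimate, with the raw-sum reading available via `normalize=False`.
  The choice does not affect the default objective's minimizers beyond an
  overall reweighting of the two terms, but it makes STSM comparable
  across J.
- One perturbation set is drawn per training run and shared by every
  instance and epoch: the estimator's offsets carry no instance index, and
  a fixed set makes the objective a deterministic function of the
  parameters (and training bit-reproducible given the seed).
- `stsm` short-circuits to exactly 0 at Q = 0; recomputing the perturbed
  pass would otherwise return BLAS rounding noise (~1e−32).
- RBF squared distances use direct elementwise differences (`cdist`), not
  the expanded inner-product form, so a code equal to a center activates
  at exactly 1.
- k-means clusters that end up empty, singleton, or made of bit-identical
  codes have no usable spread; their width falls back to the mean width of
  the non-degenerate clusters (0.1 if none).  "No usable spread" is
  width ≤ 1e−6 — on zero-noise data clusters of identical codes produce
  widths of ~1e−16 of pure floating-point noise, which would collapse the
  Gaussians.
- The output layer with ridge = 0 solves the minimum-norm least-squares
  problem (`lstsq`) rather than the normal equations: the
  exact-interpolation configuration (r = N, identity-like activations plus
  a bias column) is rank-deficient yet consistent, and the min-norm
  solution interpolates it exactly.  With ridge > 0 the regularized normal
  equations are used.
- Ties in the greedy search and in argmax decoding both break toward the
  smaller index, deterministically.
- Support-weighted F1 is the normalized form `Σ ST_i·F1_i / Σ ST_i`; the
  unnormalized sum sometimes printed for it exceeds 1 and cannot be the
  percent-scale quantity reported alongside it.  Report tables round
  half-up to integer percent.
- Welch's unequal-variance t-test is the default comparison
  (pooled-variance by flag); two zero-variance samples with equal means
  return t = 0, p = 1 by convention.

## Synthetic data: what it emulates and what it does not

The generator draws one binary prototype per activity (each bit set with
probability `prototype_density`, non-aliased prototypes forced pairwise
distinct) and emits each instance as its class prototype with independent
per-bit flips at rate ρ.  Defaults (d = 12 sensors, p = 9 activities, 27
instances per class, density 0.4, ρ = 0.05) mirror the scale of published
per-instance smart-home corpora (a few hundred instances, 10–21 sensors,
7–11 activities).  `aliased_pairs` forces chosen classes to share a
prototype, reproducing the breakfast/lunch/dinner/snack failure mode where
distinct activities have identical sensor signatures; `asymmetric_noise`
restricts flips to 1→0 (missed activations); `inject_faults` adds
label-preserving bit flips post hoc.

What it deliberately does not model: time stamps, activity durations,
ordering between activities, sensor-specific failure rates, or correlated
(multi-bit) faults.  Instances are exchangeable rows.  Consequently,
passing tests on synthetic data demonstrate that the machinery —
estimator, gradients, clustering, greedy selection, CV protocol — is
correct and that the pipeline recovers planted structure under independent
bit-flip noise; they do not certify accuracy levels on real corpora, whose
noise is structured and whose class geometry is not prototype-plus-flips.

## Problem sizes used in checks

The separable-structure check runs repeated 10-fold CV with 2 repeats on
N = 200 (d = 12, p = 6, ρ = 0) — enough folds to exercise the whole
protocol while keeping a full run of the suite in minutes.  The greedy
contract is checked on a 100-instance fixture over its entire candidate
grid (r = 5…50); the hidden-width sweep runs the {20…140} grid at k = 3
with shortened training, since only the protocol's shape is being
exercised there.  The Monte-Carlo oracle for the sensitivity estimator
uses 10⁴ uniform samples, giving a sampling error well under the 10%
agreement band being checked.

## Known limitations

- Single-hidden-layer autoencoder only; no stacking, no denoising-style
  corruption schedules.
- Centers and widths are not gradient-refined after k-means, and outputs
  are uncalibrated scores, not probabilities.
- The greedy search trains ⌊N/2⌋ − p + 1 networks; for corpora much beyond
  a few thousand instances the `step` parameter (or a smaller `r_max`) is
  the intended relief valve.
- The reader ingests per-instance binary vectors; segmenting raw
  time-stamped event streams into instances is out of scope.
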