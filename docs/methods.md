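# Methods

## Model and procedure

The package addresses cross-subject transfer in EEG emotion recognition.
Its working assumption is that, within one subject, differential-entropy
(DE) features are approximately class-conditional Gaussian, and that
subjects differ by an invertible affine "style": the new (target) subject's
features are related to a style-free source space by `t = A_s x + b_s`.
Under that assumption a single affine correction, estimated from a few
labeled calibration sessions, suffices to re-use a source-trained
classifier.

The pipeline has three stages.

**Instance selection.** A probe classifier `C0` — a one-vs-one soft-margin
SVM with Platt-calibrated, pairwise-coupled probability outputs — is
trained on the target's labeled calibration set `T_L` (features z-scored
with a scaler fitted on `T_L`). Each source sample is scored by the
probability `C0` assigns to the sample's own label; per emotion class the
`k` highest-scoring samples are kept (stable sort, ties broken by original
source order). Scoring against a target-trained probe keeps the retained
pool target-like; per-class quotas keep it balanced. An alternative score
(maximum class probability regardless of label) is available as
`score_mode="max_prob"`.

**Simplified style transfer mapping.** On the selected instances, per-class
means `μ_c` and covariances `Σ_c` are computed; covariances use the
maximum-likelihood (divisor `n`) form with linear shrinkage
`Σ_c ← (1−λ)S + λ(tr S/m)I`, which guarantees positive definiteness even
when the class count is below the feature dimension `m` (up to 310 for
62-channel, 5-band data). Each calibration sample `t` with label `c` is
assigned a Gaussian-model target point

    o = μ_c + min(1, ρ_c/d) (t − μ_c),   d = √((t−μ_c)ᵀ Σ_c⁻¹ (t−μ_c)),

i.e. samples within Mahalanobis distance `ρ_c` of the class mean are kept
as they are, and outliers are pulled back onto the `ρ_c` ellipsoid. The
affine map is then the unique closed-form minimizer of

    Σ_i f_i ‖A oⁱ + b − t_Lⁱ‖² + β‖A − I‖_F² + γ‖b‖²,

obtained from the stationarity conditions (`f̂ = Σf_i + γ`,
`P = Σf_i oⁱoⁱᵀ − ôôᵀ/f̂ + βI`, `Q = Σf_i t_Lⁱoⁱᵀ − t̂ôᵀ/f̂ + βI`,
`A = QP⁻¹`, `b = (t̂ − Aô)/f̂`). `P` is symmetric positive definite for
any `β > 0` because `γ ≥ 0` implies `f̂ ≥ Σf_i`; the system is solved by
Cholesky factorization, never by forming `P⁻¹`. The hyperparameters are
*fixed* (`β = 0.2`, `γ = 2`) rather than re-estimated iteratively — the
simplification that makes calibration fast enough for real-time use. At
test time unlabeled target rows are moved to the source space with the
inverse map `u′ = A⁻¹(t − b)` (linear solve; refused with advice to raise
`β` if `cond(A)` exceeds a cap), and classified by an SVM trained on the
selected instances plus the inverse-mapped calibration rows.

**Evaluation.** Leave-one-subject-out: each subject in turn is the target;
all sessions of all other subjects form the source pool. The calibration
set is whole sessions from the front of the target's recording until every
emotion class has appeared (at least three sessions for three-class data,
where stimuli alternate and three sessions cover the classes); the split
never cuts inside a session. Accuracy is the fraction of correctly labeled
test rows, reported per subject and as mean ± population std across
subjects. For SEED-scale data the calibration/test row counts implied by
this rule are 674/2,720 (SEED), 499/323 (SEED-IV) and 330/2,165
(14-channel three-class recordings); these are documentation constants,
not assertions, since they depend on external datasets.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | none (all) | per-class selected instances; dataset-scale dependent (600 in the synthetic benchmarks = half the per-class pool; thousands on SEED-scale data) |
| `β` | 0.2 | pull of `A` toward identity; fixed, with `γ`, instead of iterative updates |
| `γ` | 2 | pull of `b` toward zero; also enters `f̂`, so it damps the offset estimate |
| `λ` (shrinkage) | 0.1 | covariance regularization; mandatory PD check |
| `ρ_c` | class-mean distance | per-class clamp radius = mean Mahalanobis distance of calibration class-`c` samples, so roughly half of each class is left unmoved; `source_model` (`ρ_c = √m`) and `fixed` scalar modes available |
| `f_i` | 1 | correspondence confidence; calibration labels are treated as ground truth. `gaussian` mode (`exp(−d²/2m)`, max-normalized) down-weights outliers |
| kernel / C | linear / 1 | both SVMs; linear is fast and robust for DE features after z-scoring; RBF switchable |
| condition cap | 1e10 | refuse to invert a numerically singular style map |
| bands | δ 1–4, θ 4–8, α 8–14, β 14–31, γ 31–50 Hz | the conventional five EEG bands, giving `m = 310` at 62 channels; configurable |
| DE window | 1 s | per-segment feature resolution |
| broad filter | 0.1–50 Hz, notch 50 Hz | standard consumer-EEG preprocessing; mains frequency configurable |

All randomness (SVM probability calibration, synthetic generation) derives
from a single run seed via a stable per-stage hash.

## Numerical choices

- The broad band-pass is implemented as drift subtraction plus a low-pass:
  a direct IIR high-pass at 0.1 Hz (normalized frequency ~4e-4 at 256 Hz)
  has poles so close to the unit circle that zero-phase filtering amplifies
  round-off into artifacts larger than the signal. The sub-band drift is
  instead estimated on a decimated copy (where the normalized cutoff is
  healthy), resampled back and subtracted; the 50 Hz edge is an order-8
  zero-phase Butterworth low-pass (order 4 leaves a 60 Hz tone at ~19% RMS
  after forward-backward filtering — too shallow to call the band a
  stop-band). Per-band DE filters are order-4 band-passes, the standard
  choice for bands that sit well inside Nyquist.
- DE uses the time-domain sample variance of the band-filtered segment;
  a periodogram-integration estimator is available (`estimator="psd"`) and
  agrees up to filter roll-off and spectral leakage. Zero-variance
  segments are clamped at `1e-12` with a warning instead of returning −∞.
- `d = 0` in the Gaussian map yields clamp factor 1 (the sample is its own
  target point). Selection ties are broken by original source order, which
  makes selection reproducible and permutation behavior documented.
- Predicted labels are the argmax of the calibrated probabilities, keeping
  labels and probability rows mutually consistent (libsvm's raw vote can
  disagree with the coupled probabilities near ties).
- Result JSON files contain the full configuration echo and seed and are
  written with sorted keys; repeated runs with one seed are byte-identical
  (per-stage wall times are logged, not serialized, for that reason).

## The synthetic cohort generator

`synthetic_data.make_cohort` emulates exactly the structure the method
assumes: latent class-conditional Gaussians (`x ~ N(μ_c, Σ)`), per-subject
invertible styles `A_s = R(θ_s)·diag(exp(δ_s))` (random rotation of
Gaussian-random angle, log-normal axis scales) with shift `b_s`, iid
measurement noise, and contiguous same-label sessions in alternating class
order so the calibration-split rule is exercised realistically.
`make_raw_cohort` additionally emits band-limited raw EEG whose per-band
power depends on the class, for end-to-end tests of DE extraction.

Default study conditions: 6 subjects, 3 classes, `m = 10`, 12 sessions of
60 samples per subject (~4,320 rows), unit within-class covariance, class
means drawn with sd 1.2 per coordinate, `rotation_scale = 1.2` rad,
`log_scale_sd = 0.3`, `shift_sd = 5`, `noise_sd = 0.3`. The style severity
was chosen so that a pooled source-trained classifier visibly degrades on
a held-out subject (LOSO ~80%) — the cross-subject regime the method
exists for — while remaining fully recoverable by an affine correction.
Milder styles leave nothing to adapt; the zero-style limit is kept as a
test that adaptation then changes nothing.

What the generator does **not** emulate: non-Gaussian or heavy-tailed
features, within-session temporal autocorrelation, electrode artifacts,
session-to-session drift within a subject, or non-affine subject
differences. Passing tests on these cohorts therefore demonstrate
correctness of the algorithm under its own model assumptions, not
performance on real EEG.

## Benchmarks and design choices where the design was open

- **Instance score.** The method's score is written as an accuracy-like
  functional of the probe but described as a probability; the implemented
  default is the probability of the sample's own label (a sample is
  informative if the target-trained probe recognizes it as its labeled
  emotion), with `max_prob` as a switch.
- **Target-point rule.** The clamp is implemented as
  `min(1, ρ_c/d)·(t−μ_c)` added to `μ_c`: a scalar factor on the deviation,
  which is the only dimensionally coherent reading consistent with ρ's
  stated role (controlling the deviation of `o` from `μ_c`) and with
  near-mean samples being kept unchanged.
- **Offset normalizer.** `f̂` is `Σf_i + γ`: this is the exact stationarity
  solution of the objective (a multiplicative `Σf_i·γ` would zero the
  offset formula as `γ → 0`), and it is what the solver-vs-optimizer
  benchmark verifies to relative 1e-6 over random instances.
- **Style-recovery benchmark.** The pipeline's own target points are
  shrunk versions of the calibration samples, so fitting `(O, T_L)` does
  not — and should not — return the generative style itself (with a
  constant clamp factor α the exact unregularized minimizer is `A = I/α`).
  The generator↔solver consistency benchmark therefore fits the map
  between the generator's latent pre-style samples and the emitted rows
  (`β = γ = 0`, `n ≈ 2000`, `m = 6`) and checks `‖Â A_s⁻¹ − I‖_F < 0.1`:
  it validates that the solver inverts exactly the distortion the
  generator applies.
- **Which map is applied at test time.** The learned `A, b` maps
  source-space target points to the target's space; test data is moved
  with the inverse map into the source space, where the source-trained
  classifier lives. (Mapping the source forward instead is the equivalent
  alternative; the inverse form matches the convention that the mapped
  test features, not the source pool, are the derived quantity.)
- **Final training set.** By default the final classifier sees the
  selected instances plus the inverse-mapped calibration rows (they live
  in the source space after adaptation and are genuinely labeled);
  `sel_only` is retained for the ablation.
- **Ablations on synthetic cohorts.** Across ten seeded cohorts the full
  method is at least as accurate on average as either single-component
  ablation, and beats the no-adaptation baseline on at least 9/10 cohorts.
  One real-data regularity is *not* reproduced at this scale: with only
  five source subjects, instance selection alone (~94%) nearly matches the
  full method, and mapping alone (~81%) adds little over the baseline
  (~80%), because class statistics pooled over a handful of strongly
  styled subjects are a poor Gaussian model, whereas the selected,
  target-like instances are informative by themselves. With many source
  subjects and milder per-subject differences (the SEED-scale regime), the
  mapping contributes more and selection alone less.

## Known limitations

- All guarantees are conditional on the affine-style, Gaussian-class
  model; real EEG violates it to varying degrees.
- A single global affine map cannot express class-dependent distortions;
  strongly non-affine subject differences degrade gracefully toward the
  `β, γ` regularized identity but are not corrected.
- The probe is trained on very little data (a few sessions); its
  probability calibration is correspondingly coarse, which adds variance
  to the selection for small `k`.
- Desk-scale problem sizes are used throughout the benchmarks (`m ≤ 10`,
  thousands of rows); they exercise every code path, but runtime and
  accuracy at `m = 310` with tens of thousands of source rows should be
  measured on real feature files.
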