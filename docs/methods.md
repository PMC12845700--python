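# Methods

This note documents the models, numerical choices, and open design
decisions behind `frozenemg`, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and preprocessing

The pipeline targets low-rate sEMG (100 Hz), where discriminative
gesture information concentrates in the 0–1 Hz amplitude-envelope band.
A first-order Butterworth low-pass at 1 Hz is applied zero-phase
(forward–backward), so its effective magnitude response is the squared
one-pass response and no group delay shifts segment boundaries. The
filter order, cutoff and the 1100-sample standard window are fixed
protocol constants; truncation keeps the segment head because onset
dynamics carry the gesture.

### GLR boundary refinement

Manual motion labels err by tens of samples. Each channel is modelled
as a zero-mean Gaussian whose variance switches between rest and
motion; for a candidate boundary t inside a search window the GLR
statistic is the gain of the two-segment maximised log-likelihood over
the one-segment fit, computed from second moments only
(`cost(i,j) = (j−i)/2 · log(mean(x²) + ε)` with a relative floor
ε = 1e−12 × window power, which keeps noise-free windows finite).
Onset and offset are scanned independently (two linear-time one-change
scans); the window extends 25% of the segment length per side, clipped
at neighbouring labelled runs and recording edges. A change is accepted
only when its gain exceeds a BIC-style penalty `log(n)`; on stationary
noise no candidate passes and the raw bounds are kept. Channel
detections are fused by voting: earliest onset, latest offset — a
deliberate bias toward complete motion segments over tight ones.

**Placement choice.** The scan runs on the *unfiltered* signal. The
zero-phase 1 Hz filter smears the rest/motion variance transition over
roughly 30 samples, and refinement on the filtered signal measurably
*increased* boundary error on synthetic data (median 40 vs 15 samples),
whereas on the raw signal it reaches ~1 sample. Since x² = |x|², the
second-moment GLR is indifferent to rectification; only the low-pass
placement matters. Refined bounds then cut the filtered signal for
feature extraction.

## Variational mode decomposition

The ADMM iteration in the frequency domain: mode update
`û_k ← (f̂ − Σ_{j≠k} û_j + λ/2) / (1 + 2α(ω − ω_k)²)`, centre-frequency
update by the spectral centroid of |û_k|² over positive frequencies,
multiplier update `λ ← λ + τ(f̂ − Σ û_k)`. Defaults K = 2, α = 2000
(normalised-frequency units), τ = 0, tol = 1e−7, max 500 sweeps.
With τ = 0 the multiplier update is inert and λ stays exactly at its
zero initialisation — implemented literally; exact reconstruction is
then not enforced by dual ascent but recovered by amplitude
calibration.

Numerical choices: mode spectra initialise at zero, centre frequencies
uniformly over (0, fs/4], λ = 0; the signal is mirror-extended to twice
its length before the FFT and cropped after inversion to suppress
boundary artefacts; convergence is the summed relative spectral change
Σ_k ‖û_k⁽ⁿ⁺¹⁾−û_k⁽ⁿ⁾‖²/‖û_k⁽ⁿ⁾‖². Modes are returned sorted by
ascending centre frequency.

Refinements: (1) DC correction — the mean is removed first and re-added
to the lowest-frequency mode, keeping higher modes zero-mean; (2)
full-length least-squares amplitude calibration
`min_a ‖x − Σ a_k u_k‖²` via the normal equations (tiny-ridge fallback
when the mode Gram matrix is singular), which can only reduce the
reconstruction error; (3) quality indicators — relative L2
reconstruction error, per-mode energy ratios, and a fallback flag
raised above a 10% error threshold or on non-convergence, in which case
the filtered channel itself substitutes for the selected mode
downstream.

## Mode selection

Indicators per mode: energy ratio E, Pearson correlation ρ with the
original signal (0 with a warning for constant modes), and sample
entropy S (m = 2, r = 0.2·SD, Chebyshev distance, self-matches
excluded; an undefined logarithm returns the sentinel ln(#pairs), the
largest resolvable value — the field-standard convention, chosen here
because no parameters are prescribed by the protocol). Indicators are
min–max normalised across the K modes of one channel, with the
degenerate-range case (max = min, e.g. K = 1) mapped to the neutral
value 0.5. The combined score uses weights (0.4, 0.4, 0.2) on
(ρ', E', 1−S'). The normalised energy E' enters the score by default
for internal consistency with the other two normalised indicators; a
`use_raw_energy` switch provides the raw-E variant. Ties rank toward
the lower mode index. One mode per channel is retained (the IMF branch
consumes exactly one series per electrode).

## Frozen convolution features

Both branches share the architecture — modules (k, d) ∈
{(3,1), (5,3), (11,8)}, 256 filters, same padding d(k−1)/2 (k must be
odd so padding is exact) — but draw independent weights from one seeded
stream (raw branch first), w ~ N(0, 2/(C_in·k)) (Kaiming normal),
biases zero so the PPV statistic depends on the signal alone.
Convolution is dilated cross-correlation (no kernel flip, the
deep-learning convention). Parameter accounting at defaults:
256·(10k+1) = 7936 / 13 056 / 28 416 per module, 49 408 per branch,
98 816 frozen parameters total.

Feature ordering is a frozen contract: within a module GAP block then
PPV block (256 + 256 = 512); modules in configuration order (1536 per
branch); raw branch before IMF branch (3072 fused). PPV counts strictly
positive activations, so both zero inputs and ties at zero yield 0.

## Ridge readout and evaluation

`W = (DᵀD + αI)⁻¹DᵀY`, α = 0.039, one-hot Y, no intercept column —
per-feature z-scoring (fitted on training data only, on by default)
supplies the centering an intercept would; GAP and PPV live on
different scales and α is small, so scaling materially improves
conditioning. When n < d the algebraically identical dual form
`W = Dᵀ(DDᵀ + αI)⁻¹Y` is solved (n×n instead of d×d); α = 0 with a
singular Gram matrix falls back to the minimum-norm pseudoinverse.
Prediction is the argmax score, ties to the lowest class index.

Metrics: global accuracy; macro-averaged precision, recall, F1
(absent-class rates defined as 0); the multiclass-generalised MCC from
the confusion matrix — macro/multiclass forms are an explicit choice
since only binary formulas are prescribed and the task has 52 classes.
All reported on the percent scale. Paired comparison uses the exact
two-sided McNemar binomial test on discordant counts (p = 1 with none)
and Holm step-down adjustment with monotonicity enforcement.

## Protocol

Repetitions {2, 5, 10} test, the rest train. Five runs with seeds
{42, 123, 777, 2024, 2025}, each seed drawing the frozen bank; within
each run, five-fold cross-validation on the training repetitions,
group-aware so no repetition straddles folds (falling back to
sample-level folds with a warning when groups are scarce); then a final
fit on the full training split and test metrics. Everything downstream
of the seeds is deterministic, so a results bundle plus its embedded
config reproduces every number exactly.

## Synthetic generator

The generator emulates the structural features the pipeline depends
on — not sEMG physiology. Each class owns a spectral template: a
dominant frequency on a deterministic grid across 0.1–1.0 Hz plus 1–3
random secondary components, rendered per execution as a rectified
sinusoid sum with fresh random phases and ±20% amplitude jitter, scaled
by a fixed per-class per-channel gain profile (spread 0.3). Rest is
zero-mean Gaussian noise (SD 0.2, signal units; a calibration-free
choice, **not** claimed to match any real acquisition). Motion lasts
900 ± 120 samples, rest 300 ± 50, at 100 Hz. Stored labels are shifted
from true boundaries by uniform ±30-sample jitter, the true boundaries
kept for scoring. Defaults: 10 channels, 8 classes, 10 repetitions.

Not emulated: motor-unit action potentials, electrode placement and
crosstalk, fatigue and non-stationary drift, inter-subject variability.
Passing the synthetic benchmark therefore shows the pipeline's
machinery is correct and that spectrally separated envelope classes are
recovered through the full chain; it does not predict accuracy on real
recordings. The benchmark sits at desk scale (80 segments) so the whole
multi-seed run completes in minutes on one CPU; at these conditions the
classes are separable enough that fused and single-statistic feature
sets all reach the accuracy ceiling, and the fused-at-least-matches
ordering holds as ties.

## Known limitations

- The GLR model assumes an abrupt variance change; slow-ramp onsets
  bias detections late.
- VMD's α and K are fixed; highly non-stationary channels fall back to
  the filtered signal rather than adapting the decomposition.
- With τ = 0, reconstruction quality rests entirely on the Wiener-style
  updates plus calibration; pathological spectra can trip the fallback.
- The ridge readout is linear in the frozen features; class structure
  not exposed by GAP/PPV statistics of random convolutions is invisible
  to it.
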