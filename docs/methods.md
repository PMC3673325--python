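# Methods

## Model and assumptions

The recorded single-lead ECG is modeled as an additive mixture
`x(k) = ecg(k) + b(k) + p(k) + n(k)`: the cardiac signal, baseline wander
`b` confined to roughly 0.05–0.5 Hz, optional powerline interference `p` at
60 Hz, and broadband measurement noise `n`. The central assumption is that
the wander originates from a source statistically independent of the
cardiac activity, so blind source separation can isolate it without a
morphological model of the beats. Because only one lead is available, a
pseudo-multichannel observation is manufactured by delay embedding; any
linear combination of delayed copies is an FIR-filtered version of the
original, so an ICA "component" of the embedding is a filtered rendition of
one latent source — which is exactly what a baseline estimator needs.

## Pipeline

1. **Optional 60 Hz adaptive notch** (off by default; enable when powerline
   interference is present).
2. **DC-mode adaptive notch.** The LMS canceller with a constant reference
   converges to a notch at 0 Hz; its *cancelled* path `y` is a
   low-frequency sub-signal containing the wander plus whatever sub-band
   cardiac energy leaks through. Working on this sub-signal, rather than
   the raw ECG, keeps the embedding's covariance dominated by the wander.
3. **Delay embedding**: 60 channels delayed 10 samples in succession
   (span 590 samples = 1.18 s at 500 Hz). Rows are truncated to the common
   support — no zero padding, which would inject artificial steps that the
   ICA would latch onto.
4. **Fixed-point ICA** with PCA dimension reduction at the whitening step
   (see "Retained dimensions" below) and deflationary one-unit extraction.
5. **Selection**: each component is scored by the fraction of its
   periodogram power below `f_cut` = 0.8 Hz. Components clearing
   `min_selection_score` = 0.5 are baseline candidates.
6. **Adjustment**: for every candidate, and for every integer shift in
   `[0, 2·span]`, the affine fit `gain·component(k − shift) + elevation`
   to a low-frequency target is solved in closed form; the candidate/shift
   pair with the smallest mean squared residual wins. The shift compensates
   the embedding group delay (empirically a few tens to a few hundred
   samples, consistent with the half-span ≈ 295 samples); gain and
   elevation absorb ICA's sign/scale indeterminacy and the component's
   offset relative to the channel mean.
7. **Subtraction**: `clean = x − baseline`, with the adjusted baseline held
   at its edge values outside the fitted overlap.

In **reference mode** the adjustment target is a reference baseline (by
default the LOWESS trend), matching the evaluation setting in which
error₁/error₂ are defined. In **blind mode** (the deployment default) the
target is a zero-phase 4th-order Butterworth low-pass of the input below
`f_cut`; the target only steers shift/gain/elevation — the baseline's
waveform still comes from the ICA component.

Because shift 0 with freely fitted gain and elevation is always in the
search set, the adjusted error never exceeds the unadjusted one
(error₂ ≤ error₁ by construction). Both errors are evaluated on their
overlap regions: error₁ on the zero-shift overlap of the raw component with
the target, error₂ on the winning shift's overlap.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| DC notch N, ∂, C | 10 000, 1e-4, 0.1 | taps, –, – | gives BW = N∂C²/2T ≈ 2.5 rad/s ≈ 0.4 Hz, the conventional drift cut slightly below 0.5 Hz |
| 60 Hz notch N, ∂, C | 2048, 1e-3, 0.1 | | BW = 5.12 rad/s (≈ 0.81 Hz) — a sharp powerline notch |
| embedding | 60 × 10 | channels × samples | 1.18 s span: long enough to give ICA phase diversity across the wander band, short enough that any component is a gently filtered copy of the sub-signal |
| `n_components` | 5 | – | see below |
| ICA contrast | g₁, a₁ = 1 | – | robust general-purpose choice; a₁ ∈ [1, 2], a₂ ≈ 1 honored as defaults |
| ICA tol / max_iter / restarts | 1e-6 / 500 / 3 (library), 200 / 1 (pipeline) | – | direction convergence \|⟨w′, w⟩\| > 1 − tol; the pipeline's trailing components are near-Gaussian and routinely exhaust the budget without affecting baseline selection, so it uses a smaller budget |
| `f_cut` | 0.8 | Hz | above the 0.5 Hz wander band edge but below beat-rate harmonics |
| shift range | [0, 1180] | samples | twice the embedding span: covers the group delay with margin |
| LOWESS span / degree / robust iters | 1500 / 1 / 2 | samples | 3 s at 500 Hz; canonical local-linear with two bisquare rounds |
| divergence guard | 1e12 | weight norm | converts silent LMS blow-up into a diagnosable error with the sample index |

**Retained dimensions (`n_components` = 5).** `n_components` is implemented
as PCA truncation at the whitening step: the leading eigen-directions are
kept and one unit is extracted per retained dimension. Two failure modes
motivated the small default, both observed on synthetic records. Extracting
units inside the *full* 60-dimensional whitened space amplifies near-floor
noise directions to unit variance, and the extractor then returns broadband
components with no low-frequency candidate at all. With a generous
truncation (≈ 20), the fixed-point iteration instead carves the wander into
independent narrowband pieces — sinusoids at distinct frequencies are
legitimately independent sources — and no *single* component tracks the full
drift. The wander concentrates in the few leading variance directions of the
embedded sub-signal, so retaining five dimensions keeps it coherent in one
component while leaving room for cardiac leakage to separate out.

**Candidate-fit selection.** Several components routinely tie with
near-unity low-frequency scores; the spectral score cannot rank them. The
pipeline therefore adjusts every confident candidate and keeps the one with
the smallest fitted residual — a blind model-selection step that needs no
ground truth.

**Wander-free records.** When no component clears the selection threshold
the record is treated as wander-free: a warning is emitted, the report flags
`baseline_found: false`, and the adjustment proceeds anyway — the affine fit
against the (tiny) low-frequency target drives the gain toward zero, so the
input passes through essentially unchanged. Raising an error here would make
the tool fail on exactly the clean recordings it should leave alone.

## Numerical choices

- **LMS start-up.** Weights start at zero, so the identity
  `output + interference_estimate = primary` holds from sample 0 (to
  floating-point rounding). For `lms_cancel` with a user-supplied reference
  the tapped delay line is zero-padded before k = 0. `notch_filter`
  synthesizes its own deterministic sinusoidal reference and therefore
  pre-fills the delay line with the reference's analytic continuation
  (samples −(N−1)…−1); only the weight-adaptation transient (order 1/BW
  seconds) remains. This matters when the record is no longer than the tap
  count, as in the 10 000-sample truncation experiment.
- **Stability.** The adaptation constant must stay below 1/λ_max of the
  reference correlation matrix; `stability_limit` estimates λ_max by power
  iteration with FFT Toeplitz matvecs and `lms_cancel` warns when the step
  exceeds it. The weight-norm guard turns actual divergence into a
  `DivergenceError` carrying the sample index (norm checked every 64
  samples).
- **β singularities.** β = sin(N·w_rT)/sin(w_rT) is evaluated by its
  L'Hôpital limit N·cos(N·w_rT)/cos(w_rT) whenever |sin(w_rT)| < 1e-9,
  giving β → N at w_rT → 0.
- **Whitening** uses the symmetric form D V^{−1/2} Dᵀ at full rank and the
  reduced rectangular form V_r^{−1/2} D_rᵀ after truncation; eigenvalues
  below 1e-12 of the largest are dropped with a rank warning. Covariances
  use the n−1 normalization throughout.
- **E{G(v)}** in the negentropy approximation is computed by 96-node
  Gauss–Hermite quadrature, not Monte Carlo, so the estimate's only noise
  comes from the data.
- **LOWESS conventions**: windows of exactly `span` samples, symmetric in
  the interior and sliding to stay in-bounds at the edges (no reflection);
  tricube weights on distance scaled by the farthest in-window point;
  robustness weights bisquare of residual/(6·median|residual|); local
  normal equations centered at the fit point. If robustness zeroing leaves
  fewer points than coefficients, the fit degrades to the local weighted
  mean. The per-point solver is an explicit small linear solve inside a
  compiled kernel; the test suite pins it to an independent brute-force
  weighted-least-squares oracle at 1e-8.
- **Ties** in shift selection break toward the smaller shift; ties in
  component scores toward the lower index.

## Synthetic data: what it does and does not emulate

The generator emulates a 500 Hz single-lead acquisition: Gaussian-bump
P-QRS-T beats (textbook lead-II amplitudes; R normalized to 1) at RR
intervals with 2 % beat-to-beat jitter; per-record mean removal of the clean
ECG, mirroring AC-coupled front ends; wander as three sinusoids inside
0.05–0.5 Hz whose absolute amplitudes sum to the stated wander amplitude,
optionally shaped by a piecewise-linear envelope (the slowly drifting
amplitude regime); optional 60 Hz interference; white Gaussian noise with
σ = 0.02 (2 % of R). The default evaluation suite keeps the default beat
template and 72 bpm rate and varies the wander amplitude uniformly over
0.5–2× R with random phases and seeds; the broader `lbnp_like_suite` draws
wander frequencies across the band, Dirichlet amplitude splits, amplitudes
0.2–3× R, heart rates 60–90 bpm, and drifting envelopes.

What it does *not* model: ectopic beats and morphology changes,
respiration-modulated QRS amplitude, genuinely broadband or step-like
electrode artifacts, and muscle noise. Passing tests therefore demonstrate
correct separation when the wander is band-limited and additive — the
model's own assumption — not robustness to pathological rhythms.

## Problem sizes

Evaluation runs use 20 records of 60 s at 500 Hz (30 000 samples) for the
main suite, 10 drifting-envelope records truncated to 10 000 samples for
the segmentation experiment, 5 drift-free records for morphology
preservation, a 60 s white-noise probe for the empirical notch response
(cross-spectral H1 estimator, 5000-sample segments), and 10 seeded 3-source
mixtures of 5000 samples for ICA recovery.

## Known limitations

- A single adjusted component represents the baseline. When the wander
  genuinely contains several comparable independent narrowband sources, one
  component cannot carry them all; the candidate-fit selection picks the
  best single representative (the small retained dimension makes this case
  rare but cannot eliminate it).
- The blind-mode target is itself a low-pass trend; wander components right
  at the 0.8 Hz boundary are followed only weakly.
- Shifts are integral samples; sub-sample group delay is absorbed by the
  gain fit rather than interpolated.
- The LMS notch assumes a stationary interference frequency; tracking a
  drifting powerline tone is out of scope (run two passes for two tones).
- Delay spacing is specified in samples, not milliseconds, so the embedding
  span scales with the sampling rate.
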