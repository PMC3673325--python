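# ecgdrift

Hierarchical removal of baseline wander from single-lead ECG recordings.

Baseline wander is the slow (≈0.05–0.5 Hz) drift superimposed on the ECG by
respiration, electrode-impedance changes, and body motion. A plain high-pass
cut slightly below 0.5 Hz removes it — together with genuine low-frequency
ECG content such as the ST segment. `ecgdrift` instead treats the wander as
an *independent source* and separates it out blindly:

1. **Adaptive LMS notch filter.** An N-tap noise canceller driven by a
   sinusoidal reference x(k) = C·cos(w_r kT + θ) with the update
   y_k = wₖᵀxₖ, ε_k = d_k − y_k, w_{k+1} = w_k + ∂·ε_k·x_k. Its converged
   transfer function is the sharp notch
   H(z) = (z² − 2z·cos(w_r T) + 1) / (z² − 2(1 − N∂C²/4)z·cos(w_r T) + (1 − N∂C²/2))
   with bandwidth BW ≈ N∂C²/2T rad/s. A 60 Hz configuration
   (N = 2048, ∂ = 0.001, C = 0.1) cancels powerline interference; a DC
   configuration (N = 10 000, ∂ = 0.0001) acts as a drift-tracking
   high-pass whose *cancelled* path is the low-frequency sub-signal.
2. **Delay embedding.** The single-channel sub-signal is stacked into 60
   pseudo-channels delayed 10 samples in succession, so multichannel blind
   source separation applies.
3. **Fixed-point ICA** (written from scratch): centering, eigendecomposition
   whitening z = D V^{−1/2} Dᵀ y, and the one-unit negentropy iteration
   w′ = E{z g(wᵀz)} − E{g′(wᵀz)} w with deflation, using the standard
   contrasts g₁ = tanh(a₁y), g₂ = y·exp(−a₂y²/2), g₃ = y³.
4. **Selection and adjustment.** The component whose spectrum concentrates
   below 0.8 Hz is the baseline candidate; an integer time *shift* (the
   embedding group delay), plus jointly fitted *gain* and *elevation*,
   aligns it to a low-frequency target before subtraction.

A robust locally weighted regression (LOWESS, span 1500 samples ≈ 3 s at
500 Hz, tricube weights, bisquare robustness iterations) serves as the
reference method, and the error metrics
error₁ = Σ(sig₁ − sig)²/n, error₂ = Σ(sig₂ − sig)²/n,
percentage = (error₁ − error₂)/error₁ quantify how much the adjustment
improves the raw ICA component. A synthetic-ECG generator (Gaussian P-QRS-T
beats, band-limited sinusoidal wander with optional drifting envelope,
60 Hz interference, white noise) provides exact ground truth for every
stage.

## Worked example

```sh
ecgdrift synth --duration 60 --seed 7 --wander-amplitude 1.0 -o rec.csv
ecgdrift compare rec.csv --seed 0 -o out/
```

`out/report.json` (abridged) from this exact run:

```
component_index 1
shift           126
gain            0.9607
elevation       -0.0617
error1          0.01591
error2          0.00788
percentage      0.5048
```

Reading: ICA component 1 was labeled as the baseline wander; shifting it by
126 samples (252 ms) and applying gain 0.96 / elevation −0.06 halves its
mean squared disagreement with the LOWESS reference baseline
(error₂ < error₁, a 50 % error reduction). `out/` also contains `clean.csv`
(the drift-free ECG), `baseline.csv`, and the reference method's outputs.

The same pipeline is available as a library:

```python
import ecgdrift as ed

rec = ed.generate(ed.SynthSpec(duration=60.0, seed=7))
clean, estimate, report = ed.remove_baseline(rec.mixture)
```

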