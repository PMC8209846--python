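# lrtcpipe

Long-range temporal correlations (LRTCs) in continuous MEG/EEG recordings:
a tested, reproducible pipeline for estimating scaling exponents of
narrowband amplitude envelopes and comparing them between groups.

Resting-state neural oscillations fluctuate in amplitude over seconds to
minutes, and the *persistence* of those fluctuations — quantified by the
detrended fluctuation analysis (DFA) scaling exponent α of the oscillation's
envelope — is a candidate marker of cortical excitation–inhibition balance
in clinical populations. α = 0.5 means the envelope is uncorrelated noise;
α ∈ (0.5, 1] means long-memory, power-law-decaying autocorrelation. The
package is for researchers who need the full chain: continuous-data
cleaning that preserves recording length (DFA cannot tolerate cut-out
epochs), envelope extraction, exponent estimation, and estimation-focused
group statistics — plus a synthetic-data generator with known ground truth
so every stage is verifiable without access to clinical recordings.

## Method

For a signal x(t), the envelope e(t) is the modulus of its complex Morlet
transform at frequency f (bank: 40 log-spaced frequencies, 4–40 Hz). The
fluctuation function on window size t is computed in the frequency domain:

    F²(t) = Σ_f S(f) · K_t(f) · Δf,       K_t(f) = (1 − e^(−2π²σ(t)²f²))²,
    σ(t) = c·t

where S(f) is the periodogram of the integrated (cumulatively summed,
mean-removed) envelope and K_t is a Gaussian high-pass detrending kernel
playing the role of the per-window linear detrend of classical DFA; the
classical time-domain estimator is also implemented and serves as the
validation oracle (the two agree to ≲ 0.015 in α across H ∈ [0.5, 0.9]).
α is the slope of a bisquare-robust fit of log₁₀F vs log₁₀t over window
sizes 1–60 s (above filter-induced autocorrelations, at most 20% of the
record). Group differences are summarised as the difference of group
medians with a label-permutation p-value (n = 5000) and a stratified BCa
bootstrap 95% confidence interval.

Synthetic ground truth: channels are narrowband carriers amplitude-modulated
by *exact* fractional Gaussian noise (circulant embedding) with Hurst
exponent H — the value α estimates — over a 1/f background, with optional
50 Hz line noise and injected SQUID-jump/burst artifacts for testing the
replacement procedure. See `docs/methods.md` for every numerical choice.

## Worked example

```python
import numpy as np
from lrtcpipe import (OscillationSpec, gen_modulated_oscillation, envelope,
                      dfa_fourier, fit_scaling_exponent, make_window_grid,
                      FitRange)

fs, duration = 400.0, 300.0
# 10 Hz oscillation whose envelope has Hurst exponent 0.75, SNR 10
spec = OscillationSpec(carrier_freq=10.0, envelope_hurst=0.75, snr=10.0)
series = gen_modulated_oscillation(spec, duration, fs, seed=3)

env = envelope(series, fs, freq=10.0)
F = dfa_fourier(env, fs, make_window_grid())      # 181 windows, 0.08-300 s
fit = fit_scaling_exponent(F, FitRange(1.0, 60.0))
print(f"alpha = {fit.alpha:.3f}  (true envelope Hurst = 0.75)")
print(f"robust R^2 = {fit.r2:.4f} over {fit.n_points} window sizes")

white = np.random.default_rng(2).standard_normal(int(fs * duration))
fit0 = fit_scaling_exponent(
    dfa_fourier(envelope(white, fs, 10.0), fs, make_window_grid()),
    FitRange(1.0, 60.0))
print(f"white-noise anchor alpha = {fit0.alpha:.3f}")
```

prints

```
alpha = 0.708  (true envelope Hurst = 0.75)
robust R^2 = 0.9983 over 89 window sizes
white-noise anchor alpha = 0.495
```

The fitted exponent sits near the generating Hurst exponent (finite SNR
pulls it slightly toward 0.5 — extrinsic noise is uncorrelated, which is
exactly why the package also ships the power–exponent decoupling check),
the fit is an excellent power law across the 89 window sizes inside 1–60 s,
and an uncorrelated control signal lands on the α = 0.5 anchor.

The same analysis scales to recordings and cohorts:

```python
from lrtcpipe import gen_cohort, CohortSpec, GroupSpec, lrtc_map, \
    summarize_subject, median_difference_curves, compare_groups
```

or from the shell:

```
lrtcpipe run --config config.yaml --out results/
```

which writes per-subject recordings, cleaned data, exponent maps
(HDF5 + TSV), group comparisons (JSON) and a run manifest with parameters,
seeds and content hashes.

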