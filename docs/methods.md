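# Methods

`lrtcpipe` estimates long-range temporal correlations (LRTCs) in continuous
electrophysiological recordings: the scaling exponent α of the amplitude
envelope of narrowband neural oscillations, obtained by detrended
fluctuation analysis (DFA), compared between groups with resampling
statistics. This note documents the model, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Signal model and ground truth

The synthetic generator emulates a resting-state MEG session: each channel
is a narrowband carrier (default 10 Hz) whose instantaneous amplitude is a
strictly positive transform of fractional Gaussian noise (fGn) with Hurst
exponent H, mixed with a unit-variance 1/f background at a chosen
oscillation-to-background power ratio (`snr`), plus optional 50 Hz line
interference and injected high-amplitude artifacts (persistent step
"SQUID jumps", broadband bursts at Poisson times). H is the ground truth
the fitted α estimates: H = 0.5 is an uncorrelated envelope, H in (0.5, 1)
a persistent, power-law-correlated one.

fGn is synthesised **exactly** by circulant embedding of its autocovariance
γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) (eigenvalue decomposition
of the circulant extension via FFT, embedding doubled if an eigenvalue is
negative). Filtering approximations were deliberately avoided: they distort
the autocorrelation tail that DFA measures.

The envelope-positivity transform is shift-and-clip: env = max(1 + d·z,
0.05) with z unit-variance fGn and modulation depth d = 0.3. At this depth
the clip touches < 0.1% of samples, so the envelope's scaling exponent is
essentially H; the residual distortion is measured, not assumed, by the
recovery tests. No claim is made that this is a biophysical model of
resting-state MEG — it is a stand-in with controllable ground truth, and
every generated recording records `generative_model: "stand-in"` in its
provenance.

Cohorts draw each subject's per-channel H from N(median, spread²) clipped
to [0.05, 0.95]; default desk-scale geometry is 300 s at 400 Hz (generated
directly at the post-downsample rate) with a few channels. Sensor layout is
a deterministic unit-disc spiral with +y anterior, so "posterior channels"
(y below median, or y < 0) is programmatically defined.

## Preprocessing

The cleaning chain preserves recording length end to end, because DFA needs
minutes of continuous signal: channel removal → demean → 49–51 Hz order-3
Butterworth notch (zero-phase, forward–backward) → 1 Hz Hamming-window FIR
high-pass of order 3052 (linear-phase; applied as a delay-compensated
single pass realised by reflect-padded 'same' convolution, hence exactly
zero-phase; the windowed-sinc design's residual −54 dB DC gain is nulled by
subtracting the tap mean) → polyphase anti-aliased resampling to 400 Hz
(exact rational ratio, e.g. 1600/4069 for 1017.25 → 400 Hz) → application
of a stored unmixing/mixing pair with artifact components zeroed (component
*estimation* is out of scope; the model is consumed as data) → artifact
detection and replacement.

Artifact detection replaces visual inspection: per-channel robust z-scores
(median/MAD) of the absolute first difference and of a 50 ms moving RMS of
the half-Nyquist-high-passed signal, aggregated as the max over channels;
samples with z ≥ 8 are flagged, dilated by 200 ms, and merged across gaps
shorter than 200 ms.

Replacement reconstructs flagged samples without shortening the record:
flagged samples are treated as missing; the slow trend of the available
data is a Savitzky–Golay filter (order 1, frame 41) computed per clean run;
the trend is carried across each gap by shape-preserving piecewise cubic
(PCHIP) interpolation of the clean-sample trend; the gap is filled with
that trend plus a zero-mean surrogate fluctuation. The default surrogate is
the adjacent clean segment of equal length, detrended by its own SG trend
and time-reversed (mirror mode) — continuous at the gap edge, preserving
local spectral content without duplicating exact samples; an
amplitude-matched filtered-noise surrogate is available by flag. Gaps at
the record edge fall back to one-sided trend extrapolation with a warning;
gaps longer than 4 s warn. Samples outside flagged intervals are returned
bit-identical, and replacing ~1% of a long-memory recording moves α by
less than 0.02 (tested at H = 0.8).

## Scaling-exponent estimation

Envelopes are the modulus of a complex Morlet convolution; the wavelet has
Gaussian time SD n_cycles/(2πf), support ±5 SD, and is amplitude-normalised
(a unit sinusoid at f yields envelope 1). The bank spans 4–40 Hz in 40
log10-equispaced frequencies. DFA window sizes are 181 log10-equispaced
values from 0.08 to 300 s; fits use log10 F vs log10 t restricted to 1–60 s
— above the region where narrowband-filter-induced autocorrelations steepen
the curve, and at most 20% of the record length — with a bisquare (Tukey
biweight) IRLS regression that falls back to ordinary least squares (with a
diagnostic flag) if it fails to converge.

**Classical estimator** (validation oracle): cumulative sum of the
mean-removed envelope; non-overlapping windows per size (end remainder
discarded); least-squares line detrend per window; F(t) = pooled RMS
residual. Windows shorter than 4 samples or longer than the record are
skipped and the usable-window count recorded.

**Fourier estimator** (default): F²(t) = Σ_f S(f)·K_t(f)·Δf with the
Gaussian high-pass detrending kernel K_t(f) = (1 − exp(−2π²σ(t)²f²))²,
σ(t) = c·t. S(f) is the full-length one-sided periodogram (no Welch
averaging — single-trace setting) of the integrated, mean-removed envelope.
Two numerical points matter:

* **Taper.** The integrated envelope is a random-walk-like profile whose
  spectrum reaches f^−3 for strongly persistent envelopes. A rectangular
  window's sidelobes cap measurable periodogram slopes near f^−2, which
  biases α downward by up to −0.23 at H = 0.9. The profile periodogram is
  therefore taken with a Hann taper after linear detrending; this restores
  agreement with the classical estimator to ≲ 0.015 across H ∈ [0.5, 0.9].
  An alternative integration mode ("spectral") divides the rectangular
  periodogram of the *stationary* envelope by the exact discrete-integration
  transfer (2 sin(πf/fs))²; it agrees comparably and is selectable.
* **Kernel constant.** c = `KERNEL_CONST` = 0.3 is a fixed calibration
  chosen once by scanning candidates against the classical estimator on
  exact fGn across H ∈ {0.5, …, 0.9} and checking the white-noise anchor of
  the full pipeline (`scripts/calibrate_kernel.py`). The fitted slope is
  asymptotically invariant to c; c controls where the kernel's soft cutoff
  sits relative to the fit range and hence the small-t crossover.

The kernel sum is evaluated as total power minus the complement
Σ S·(2e^{−x} − e^{−2x}), truncated where e^{−x} < 1e−14, so the 181-window
evaluation costs little beyond one FFT.

**Morlet width.** The default is n_cycles = 2. With the 1 s fit floor this
is a forced choice, not a taste: the envelope of a w-cycle wavelet carries
filter-induced autocorrelation over ~w/(2πf)·√2 seconds, whose spectral
roll-off contaminates the first decade of the fit range. At 7 cycles and
10 Hz the uncorrelated-noise anchor lands near 0.57 (classical) / 0.62
(Fourier) instead of 0.5 — the method's own sanity anchor fails. At 2
cycles the anchor is ~0.51–0.52 for both estimators and the H-recovery
ladder (0.55–0.85, high SNR) is unbiased to ≤ 0.015. The cost is broad
frequency resolution (σ_f = f/2); analyses that need sharper banks (e.g.
relative power topographies) can raise n_cycles per call, and the
white-noise anchor should be re-checked whenever it is changed.

Relative power divides the mean squared envelope by the wavelet kernel
energy (which grows ∝ f at fixed cycles) before normalising each channel
across frequencies to sum to 1, so a spectrally flat input reads flat.

## Group statistics

Subject summaries are channel-median α per frequency (optionally over a
channel subset). Median-difference curves (clinical − control, per
frequency) feed band-wise frequency-of-interest selection: within theta
(4–8 Hz), alpha (8–12 Hz) and beta (12–40 Hz, upper edge inclusive), the
bank frequency maximising the largest absolute group difference; exact ties
resolve to the lower frequency. Frequencies of interest are data outputs,
never constants.

Inference is estimation-focused. The default statistic is the difference of
group medians — the quantity reported as the effect size — with a Welch-t
variant available. The permutation test reassigns labels n = 5000 times
(Monte-Carlo with add-one correction, two-sided); with the median statistic
and odd group sizes the p-value is mildly conservative because permutation
medians tie with the observed order statistics — calibration is exact for
even sizes and the t statistic. Confidence intervals are stratified
(within-group) bootstrap with BCa correction: bias z₀ from the fraction of
resamples below the observed statistic (with a half-weight tie adjustment),
acceleration from the pooled leave-one-subject-out jackknife skewness.
P-values are reported uncorrected, matching the estimation-statistics
reporting style; Bonferroni across tested frequencies is an off-by-default
flag. All resampling derives from explicit seeds recorded in every result.

The power–α decoupling check is the Pearson correlation of subject-level
relative power against α: DFA is amplitude-invariant, so a positive
correlation indicates extrinsic (uncorrelated) noise pulling low-SNR
channels toward α = 0.5; a channel subset on which the correlation vanishes
licenses interpreting group differences there. Clinical-score associations
use Spearman rank correlations with pairwise deletion and an explicit
minimum of 3 complete pairs.

## Benchmark problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes on one CPU in minutes: 300 s single-channel
recordings at 400 Hz; 20 seeds for the anchor, detection and
estimator-equivalence checks (H ∈ {0.5,…,0.9}); 100 cohort repeats of
n = 25 vs 47 subjects (spread 0.05, true Δmedian(H) = 0.05, bootstrap
reduced to 1000 resamples) for effect-size recovery and interval coverage;
500 null simulations (n = 20 vs 20, 1000 permutations) for type-I
calibration. The cohort recovery test uses a reduced window grid
(0.5–75 s, 61 sizes) spanning the same 1–60 s fit range. The
acquisition-scale geometry (248 channels, 1017.25 Hz) is exercised
functionally (filters, resampling ratios) but not at full length in the
default suite.

## What passing does and does not show

Passing demonstrates that the estimator chain is internally consistent
(Fourier ≈ classical), correctly anchored (α = 0.5 on uncorrelated
envelopes), sensitive and approximately unbiased for power-law envelope
correlations of the kind the generator produces, robust to the replacement
procedure, and that the inference layer has nominal calibration and
coverage under the generator's assumptions (Gaussian between-subject
spread, independent channels, stationary H). It does not validate the
biophysics of real MEG: volume conduction, non-stationarity,
subject-specific spectra, real artifact morphology and sensor noise are
all outside the generator, and results on real recordings inherit none of
these guarantees automatically.

## Known limitations

* The Fourier estimator's small-t crossover is softer than the classical
  window detrend; agreement is calibrated over H ∈ [0.5, 0.9] and the 1–60 s
  fit range, not guaranteed outside it.
* n_cycles = 2 trades frequency resolution for an unbiased 1 s fit floor
  (see above).
* Median-statistic permutation p-values are conservative for odd group
  sizes.
* The replacement procedure assumes gaps are short relative to the record
  (warns above 4 s) and that adjacent segments are clean enough to donate
  fluctuation content.
* Fitted exponents outside [0.3, 1.3] trigger a soft warning only; they
  usually indicate an inappropriate fit range or pathological input.
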