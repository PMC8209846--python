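"""Scaling-exponent estimation from narrowband amplitude envelopes.

The core quantity is the detrended-fluctuation-analysis (DFA) scaling
exponent alpha of an oscillation's amplitude envelope: the slope of
log10 F(t) vs log10 t, where F(t) is the fluctuation magnitude of the
integrated envelope at window size t. alpha = 0.5 marks an uncorrelated
envelope; alpha in (0.5, 1] marks long-range temporal correlations (LRTCs).

Two estimators of F(t) are provided:

``dfa_classical``
    the time-domain construction (cumulative sum, non-overlapping windows,
    per-window linear detrend, pooled RMS residual) — used as the
    validation oracle;

``dfa_fourier``
    a frequency-domain construction: the periodogram S(f) of the integrated
    envelope is weighted by a Gaussian high-pass detrending kernel
    ``K_t(f) = (1 - exp(-2 pi^2 sigma(t)^2 f^2))^2`` with
    ``sigma(t) = KERNEL_CONST * t``, and ``F(t) = sqrt(sum_f S(f) K_t(f) df)``.
    The kernel suppresses fluctuations slower than the window, playing the
    role the within-window detrend plays in the classical construction.
    ``KERNEL_CONST`` is a fixed calibration constant chosen once to minimise
    the mean |alpha_fourier - alpha_classical| over simulated fGn envelopes
    with H in {0.5, ..., 0.9} (see scripts/calibrate_kernel.py).

Envelopes come from complex Morlet wavelet convolution over a log-spaced
bank (default 40 frequencies, 4-40 Hz); fits use a bisquare robust linear
regression on log-log coordinates over 1-60 s windows, below the 20%-of-data
ceiling and above the floor where narrowband-filter-induced autocorrelations
steepen the fluctuation function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import statsmodels.api as sm

from .containers import ContinuousRecording
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "KERNEL_CONST",
    "WaveletBank",
    "WindowGrid",
    "FitRange",
    "FluctuationFunction",
    "FitResult",
    "ScalingExponentMap",
    "make_wavelet_bank",
    "make_window_grid",
    "morlet_kernel",
    "envelope",
    "dfa_classical",
    "dfa_fourier",
    "fit_scaling_exponent",
    "lrtc_map",
    "relative_power",
]

#: Gaussian detrending-kernel width per unit window size, sigma(t) = c * t.
#: Calibrated once against the classical estimator on exact fGn
#: (scripts/calibrate_kernel.py); see docs/methods.md.
KERNEL_CONST = 0.3


# ---------------------------------------------------------------------------
# Frequency bank and window grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletBank:
    frequencies: np.ndarray  # Hz, strictly increasing
    n_cycles: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size < 1:
            raise ParameterError("frequencies must be a non-empty 1-D array")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ParameterError("frequencies must be strictly increasing")
        if f[0] <= 0:
            raise ParameterError("frequencies must be positive")
        if self.n_cycles <= 0:
            raise ParameterError("n_cycles must be positive")


def make_wavelet_bank(f_min: float = 4.0, f_max: float = 40.0, n: int = 40,
                      n_cycles: float = 2.0) -> WaveletBank:
    """Log10-equispaced Morlet frequency bank, endpoints inclusive."""
    if f_min <= 0 or f_max < f_min:
        raise ParameterError("require 0 < f_min <= f_max")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n == 1:
        freqs = np.array([f_min])
    else:
        if f_max == f_min:
            raise ParameterError("n > 1 requires f_max > f_min")
        freqs = np.logspace(np.log10(f_min), np.log10(f_max), n)
    return WaveletBank(frequencies=freqs, n_cycles=n_cycles)


@dataclass(frozen=True)
class WindowGrid:
    sizes: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=np.float64)
        object.__setattr__(self, "sizes", s)
        if s.ndim != 1 or s.size < 2 or not np.all(np.diff(s) > 0) or s[0] <= 0:
            raise ParameterError("sizes must be increasing positive 1-D array")


def make_window_grid(t_min: float = 0.08, t_max: float = 300.0,
                     n: int = 181) -> WindowGrid:
    """Log10-equispaced DFA window sizes, endpoints inclusive."""
    if not 0 < t_min < t_max:
        raise ParameterError("require 0 < t_min < t_max")
    if n < 2:
        raise ParameterError("n must be >= 2")
    return WindowGrid(sizes=np.logspace(np.log10(t_min), np.log10(t_max), n))


@dataclass(frozen=True)
class FitRange:
    """Window range of the log-log slope fit, in seconds.

    The 1 s floor avoids narrowband-filter-induced autocorrelations (visible
    as a steeper fluctuation slope below ~1 s); the ceiling defaults to 60 s
    = 20% of a 300 s recording, beyond which too few windows remain.
    """

    t_min: float = 1.0
    t_max: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise ParameterError("require 0 < t_min < t_max")

    @classmethod
    def for_duration(cls, duration: float, t_min: float = 1.0) -> "FitRange":
        """Default range for a recording: 1 s up to min(60 s, 20% of data)."""
        return cls(t_min=t_min, t_max=min(60.0, 0.2 * duration))


# ---------------------------------------------------------------------------
# Morlet envelope
# ---------------------------------------------------------------------------

def morlet_kernel(fs: float, freq: float, n_cycles: float = 2.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at ``fs``.

    Gaussian SD in time is ``n_cycles / (2 pi f)``; support is +-5 SD. The
    kernel is scaled so that convolution with a unit-amplitude sinusoid at
    ``freq`` returns an envelope of 1 (signal units preserved).
    """
    if freq >= fs / 2:
        raise ParameterError(f"freq {freq} Hz at or above Nyquist ({fs / 2})")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    norm = 2.0 / (sigma_t * fs * np.sqrt(2.0 * np.pi))
    return norm * gauss * np.exp(2j * np.pi * freq * t)


def envelope(series: np.ndarray, fs: float, freq: float,
             n_cycles: float = 2.0) -> np.ndarray:
    """Amplitude envelope: modulus of the complex Morlet convolution.

    Same length as the input ('same'-mode FFT convolution; amplitudes within
    half a kernel of the edges are attenuated because the kernel overhangs
    the record — negligible for minutes-long recordings).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise DataError("series must be 1-D")
    w = morlet_kernel(fs, freq, n_cycles)
    if w.size > x.size:
        raise DataError(
            f"wavelet ({w.size} samples) longer than signal ({x.size})"
        )
    return np.abs(scipy.signal.fftconvolve(x, w, mode="same"))


# ---------------------------------------------------------------------------
# Fluctuation functions
# ---------------------------------------------------------------------------

@dataclass
class FluctuationFunction:
    window_sizes: np.ndarray  # seconds (grid entries actually used)
    F_values: np.ndarray      # fluctuation magnitude, signal units
    method: str               # "classical" | "fourier"
    n_windows_used: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.window_sizes = np.asarray(self.window_sizes, dtype=np.float64)
        self.F_values = np.asarray(self.F_values, dtype=np.float64)
        if self.n_windows_used is None:
            self.n_windows_used = np.zeros(self.window_sizes.size, dtype=np.int64)
        if not np.all(np.isfinite(self.F_values)) or np.any(self.F_values <= 0):
            raise DataError("fluctuation values must be finite and positive")


_MIN_WINDOW_SAMPLES = 4  # linear detrend needs a margin beyond 2 points


def _check_envelope(env: np.ndarray) -> np.ndarray:
    env = np.asarray(env, dtype=np.float64)
    if env.ndim != 1 or env.size < 8:
        raise DataError("envelope must be a 1-D array of reasonable length")
    if not np.all(np.isfinite(env)):
        raise DataError("envelope contains non-finite values")
    if np.ptp(env) == 0:
        raise DataError("constant envelope: scaling exponent undefined")
    return env


def dfa_classical(env: np.ndarray, fs: float, grid: WindowGrid) -> FluctuationFunction:
    """Time-domain DFA fluctuation function (order-1 detrending).

    The mean-removed envelope is cumulatively summed; for each window size
    the profile is partitioned into non-overlapping windows (remainder at
    the end discarded), each window is least-squares line-detrended, and
    F(t) is the RMS of the pooled residuals. Window sizes needing fewer than
    4 samples or exceeding the record are skipped.
    """
    env = _check_envelope(env)
    profile = np.cumsum(env - env.mean())
    n = profile.size
    sizes, fvals, nwin = [], [], []
    for t in grid.sizes:
        ell = int(round(t * fs))
        if ell < _MIN_WINDOW_SAMPLES or ell > n:
            continue
        k = n // ell
        seg = profile[: k * ell].reshape(k, ell)
        x = np.arange(ell) - (ell - 1) / 2.0
        sxx = float(np.sum(x * x))
        slope = seg @ x / sxx
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * x
        f2 = float(np.mean(resid ** 2))
        if f2 <= 0:
            continue
        sizes.append(t)
        fvals.append(np.sqrt(f2))
        nwin.append(k)
    if not sizes:
        raise DataError("no usable window sizes for this record length")
    return FluctuationFunction(np.array(sizes), np.array(fvals), "classical",
                               np.array(nwin, dtype=np.int64))


def dfa_fourier(env: np.ndarray, fs: float, grid: WindowGrid,
                kernel_const: float = KERNEL_CONST,
                integration: str = "time") -> FluctuationFunction:
    """Frequency-domain DFA fluctuation function.

    With ``integration="time"`` (default), S(f) is the full-length one-sided
    periodogram of the integrated (cumulatively summed, mean-removed)
    envelope. The profile is a random-walk-like curve, so its periodogram is
    taken with a Hann taper after linear detrending: with a plain
    rectangular window the profile's steep spectrum (up to f^-3 for strongly
    persistent envelopes) leaks through the sidelobes and caps the
    measurable slope near 2, biasing alpha downward for H > 0.6.

    With ``integration="spectral"``, S(f) is the rectangular-window
    periodogram of the (stationary) mean-removed envelope divided by the
    exact discrete-integration transfer ``(2 sin(pi f / fs))^2``; the
    kernel's f^4 roll-off keeps the f -> 0 amplification integrable.

    F(t) then sums S(f) under the Gaussian high-pass kernel K_t(f); only
    frequencies where ``1 - K_t`` is non-negligible need be touched, so the
    sum is computed as total power minus the complement.
    """
    env = _check_envelope(env)
    if kernel_const <= 0:
        raise ParameterError("kernel_const must be positive")
    n = env.size
    if integration == "time":
        profile = np.cumsum(env - env.mean())
        freqs, S = scipy.signal.periodogram(
            profile, fs=fs, window="hann", detrend="linear"
        )
    elif integration == "spectral":
        freqs, S = scipy.signal.periodogram(
            env - env.mean(), fs=fs, window="boxcar", detrend="constant"
        )
        w2 = (2.0 * np.sin(np.pi * freqs[1:] / fs)) ** 2
        S[1:] = S[1:] / (w2 * fs ** 2)  # per-second integration transfer
    else:
        raise ParameterError(f"unknown integration mode {integration!r}")
    df = freqs[1] - freqs[0]
    total = float(np.sum(S[1:]) * df)
    sizes, fvals, nwin = [], [], []
    two_pi2 = 2.0 * np.pi ** 2
    for t in grid.sizes:
        ell = int(round(t * fs))
        if ell < _MIN_WINDOW_SAMPLES or ell > n:
            continue
        sigma2 = (kernel_const * t) ** 2
        # exp(-x) < 1e-14 for x > 33: complement support ends there
        f_cut = np.sqrt(33.0 / (two_pi2 * sigma2))
        hi = int(np.searchsorted(freqs, f_cut))
        x = two_pi2 * sigma2 * freqs[1:hi] ** 2
        e = np.exp(-x)
        complement = float(np.sum(S[1:hi] * (2.0 * e - e * e)) * df)
        f2 = total - complement
        if f2 <= 0:
            continue
        sizes.append(t)
        fvals.append(np.sqrt(f2))
        nwin.append(n // ell)
    if not sizes:
        raise DataError("no usable window sizes for this record length")
    return FluctuationFunction(np.array(sizes), np.array(fvals), "fourier",
                               np.array(nwin, dtype=np.int64))


# ---------------------------------------------------------------------------
# Robust log-log fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    alpha: float
    intercept: float
    r2: float
    n_points: int
    iterations: int
    fallback_ols: bool = False


def fit_scaling_exponent(F: FluctuationFunction,
                         fit_range: FitRange = FitRange()) -> FitResult:
    """Bisquare (Tukey biweight) robust fit of log10 F vs log10 t.

    Iteratively reweighted least squares; on non-convergence falls back to
    ordinary least squares with ``fallback_ols=True``. The reported r2 is
    weighted by the final robust weights.
    """
    sel = (F.window_sizes >= fit_range.t_min) & (F.window_sizes <= fit_range.t_max)
    if int(sel.sum()) < 3:
        raise DataError(
            f"need >= 3 windows inside fit range "
            f"[{fit_range.t_min}, {fit_range.t_max}] s, have {int(sel.sum())}"
        )
    x = np.log10(F.window_sizes[sel])
    y = np.log10(F.F_values[sel])
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(maxiter=100)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite robust fit")
        w = res.weights
        slope = float(res.params[1])
        intercept = float(res.params[0])
        n_iter = int(getattr(res, "fit_history", {}).get("iteration", 0) or 0)
        fallback = False
    except Exception:
        coef = np.polyfit(x, y, 1)
        slope, intercept = float(coef[0]), float(coef[1])
        w = np.ones_like(x)
        n_iter = 0
        fallback = True
        warnings.warn("robust fit failed; ordinary least squares fallback",
                      stacklevel=2)
    yhat = intercept + slope * x
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return FitResult(alpha=slope, intercept=intercept, r2=r2,
                     n_points=int(sel.sum()), iterations=n_iter,
                     fallback_ols=fallback)


def estimate_alpha(series: np.ndarray, fs: float, freq: float,
                   n_cycles: float = 2.0,
                   grid: WindowGrid | None = None,
                   fit_range: FitRange | None = None,
                   method: str = "fourier",
                   kernel_const: float = KERNEL_CONST) -> FitResult:
    """Single-channel, single-frequency scaling exponent.

    Convenience composition of :func:`envelope`, the chosen fluctuation
    estimator and :func:`fit_scaling_exponent` with the standard defaults.
    """
    duration = series.size / fs
    if grid is None:
        grid = make_window_grid(t_max=min(300.0, duration))
    if fit_range is None:
        fit_range = FitRange.for_duration(duration)
    env = envelope(series, fs, freq, n_cycles)
    if method == "fourier":
        F = dfa_fourier(env, fs, grid, kernel_const)
    elif method == "classical":
        F = dfa_classical(env, fs, grid)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return fit_scaling_exponent(F, fit_range)


# ---------------------------------------------------------------------------
# Channel x frequency maps
# ---------------------------------------------------------------------------

@dataclass
class ScalingExponentMap:
    """Fitted exponents for every (channel, frequency) cell.

    Failed cells are NaN with the reason recorded in ``failures``. Values
    outside the soft range [0.3, 1.3] are legal but trigger a warning, since
    valid envelope data rarely produce them.
    """

    alpha: np.ndarray        # channels x frequencies
    fit_r2: np.ndarray
    n_windows_used: np.ndarray
    frequencies: np.ndarray
    channel_names: list[str]
    method: str = "fourier"
    channel_pos: np.ndarray | None = None
    failures: dict = field(default_factory=dict)


def lrtc_map(rec: ContinuousRecording,
             bank: WaveletBank | None = None,
             grid: WindowGrid | None = None,
             fit_range: FitRange | None = None,
             method: str = "fourier",
             kernel_const: float = KERNEL_CONST) -> ScalingExponentMap:
    """Scaling exponent for every channel and bank frequency.

    Deterministic given its inputs; per-cell failures are recorded (NaN plus
    a reason) and never abort the map.
    """
    if method not in ("fourier", "classical"):
        raise ParameterError(f"unknown method {method!r}")
    bank = bank or make_wavelet_bank()
    if grid is None:
        grid = make_window_grid()
    if grid.sizes[-1] > rec.duration + 1e-9:
        warnings.warn(
            f"window grid max {grid.sizes[-1]:g} s exceeds recording "
            f"duration {rec.duration:g} s; oversized windows are skipped",
            stacklevel=2,
        )
    if fit_range is None:
        fit_range = FitRange.for_duration(rec.duration)
    nc, nf = rec.n_channels, bank.frequencies.size
    alpha = np.full((nc, nf), np.nan)
    r2 = np.full((nc, nf), np.nan)
    nwin = np.zeros((nc, nf), dtype=np.int64)
    failures: dict = {}
    dfa_fun = dfa_fourier if method == "fourier" else dfa_classical
    for c in range(nc):
        logger.info("lrtc_map: channel %s (%d/%d)", rec.channel_names[c],
                    c + 1, nc)
        for j, f in enumerate(bank.frequencies):
            try:
                env = envelope(rec.data[c], rec.fs, f, bank.n_cycles)
                if method == "fourier":
                    F = dfa_fourier(env, rec.fs, grid, kernel_const)
                else:
                    F = dfa_classical(env, rec.fs, grid)
                fit = fit_scaling_exponent(F, fit_range)
            except Exception as exc:  # per-cell isolation by contract
                failures[(rec.channel_names[c], float(f))] = str(exc)
                continue
            alpha[c, j] = fit.alpha
            r2[c, j] = fit.r2
            nwin[c, j] = fit.n_points
            logger.debug("  %6.2f Hz: alpha=%.3f r2=%.3f", f, fit.alpha, fit.r2)
    finite = alpha[np.isfinite(alpha)]
    if finite.size and (finite.min() < 0.3 or finite.max() > 1.3):
        warnings.warn("fitted exponents outside the typical [0.3, 1.3] range",
                      stacklevel=2)
    return ScalingExponentMap(alpha=alpha, fit_r2=r2, n_windows_used=nwin,
                              frequencies=bank.frequencies.copy(),
                              channel_names=list(rec.channel_names),
                              method=method,
                              channel_pos=None if rec.channel_pos is None
                              else rec.channel_pos.copy(),
                              failures=failures)


def relative_power(rec: ContinuousRecording,
                   bank: WaveletBank | None = None) -> np.ndarray:
    """Relative narrowband power per channel: mean squared Morlet envelope
    per bank frequency, normalised to sum to 1 across frequencies.

    Normalisation absorbs the orders-of-magnitude absolute-power differences
    between recordings.
    """
    bank = bank or make_wavelet_bank()
    # wavelet noise-bandwidth correction: E[env^2] for white noise equals
    # the kernel energy, which grows with the wavelet's bandwidth (~f at
    # fixed n_cycles); dividing it out makes a flat spectrum read flat
    energy = np.array([
        float(np.sum(np.abs(morlet_kernel(rec.fs, f, bank.n_cycles)) ** 2))
        for f in bank.frequencies
    ])
    power = np.empty((rec.n_channels, bank.frequencies.size))
    for c in range(rec.n_channels):
        if np.ptp(rec.data[c]) == 0:
            raise DataError(f"channel {rec.channel_names[c]} is constant")
        for j, f in enumerate(bank.frequencies):
            env = envelope(rec.data[c], rec.fs, f, bank.n_cycles)
            power[c, j] = np.mean(env ** 2) / energy[j]
    return power / power.sum(axis=1, keepdims=True)
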