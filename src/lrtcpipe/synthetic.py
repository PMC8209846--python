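"""Synthetic multichannel recordings with known envelope-autocorrelation structure.

The generators emulate the study conditions of a resting-state MEG session —
5-minute recordings containing narrowband oscillations whose amplitude
envelopes decay as a power law with a prescribed Hurst exponent, on top of a
1/f background, optional 50 Hz line interference, and injected high-amplitude
artifacts (SQUID-like step jumps, broadband bursts). Ground truth (the Hurst
exponent H of the envelope modulator) is what the pipeline's fitted scaling
exponent alpha estimates, so every downstream stage can be validated on
recovery accuracy.

No generative model of resting-state MEG is implied by the analysis method
itself; everything here is an explicit stand-in, and each generator records
its full specification (including seeds) in the recording's provenance with
``"generative_model": "stand-in"``.

Fractional Gaussian noise is synthesised exactly (circulant embedding of the
fGn autocovariance, the Davies-Harte family), not by filtering approximations:
DFA is sensitive to the autocorrelation tail, which filter cascades distort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ArtifactAnnotations, ContinuousRecording
from .errors import DataError, ParameterError

__all__ = [
    "FgnSpec",
    "OscillationSpec",
    "ArtifactSpec",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "SubjectRecording",
    "fgn_autocovariance",
    "gen_fgn",
    "gen_pink_noise",
    "gen_modulated_oscillation",
    "gen_recording",
    "inject_artifacts",
    "gen_cohort",
    "layout_positions",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FgnSpec:
    """Fractional Gaussian noise: ``hurst`` in (0, 1), H=0.5 is white noise."""

    hurst: float
    n_samples: int
    variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ParameterError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if self.variance <= 0:
            raise ParameterError("variance must be positive")


@dataclass(frozen=True)
class OscillationSpec:
    """A narrowband carrier amplitude-modulated by long-memory noise.

    ``snr`` is the ratio of oscillation power to broadband background power
    (``inf`` = oscillation only, ``0`` = background only). ``mod_depth`` is
    the standard deviation of the fGn modulator relative to the mean envelope
    amplitude of 1; the envelope is made strictly positive by clipping at
    ``0.05`` (shift-and-clip transform; with the default depth the clip
    affects <0.1% of samples, so the envelope Hurst exponent is essentially
    preserved).
    """

    carrier_freq: float = 10.0
    envelope_hurst: float = 0.75
    snr: float = 10.0
    line_noise_amp: float = 0.0
    mod_depth: float = 0.3

    def __post_init__(self) -> None:
        if self.carrier_freq <= 0:
            raise ParameterError("carrier_freq must be positive")
        if not self.snr >= 0:
            raise ParameterError("snr must be >= 0")
        if self.mod_depth <= 0:
            raise ParameterError("mod_depth must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates and magnitudes of injected high-amplitude artifacts."""

    jump_rate: float = 1.0        # step events per minute
    jump_amplitude: float = 20.0  # multiples of channel SD
    burst_rate: float = 1.0       # burst events per minute
    burst_duration: float = 0.5   # seconds
    burst_gain: float = 10.0      # burst noise SD in multiples of channel SD

    def __post_init__(self) -> None:
        if self.jump_rate < 0 or self.burst_rate < 0:
            raise ParameterError("event rates must be >= 0")
        if self.burst_duration <= 0:
            raise ParameterError("burst_duration must be positive")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: subjects draw their envelope Hurst exponent from
    N(hurst_median, hurst_spread^2), clipped to [0.05, 0.95].

    ``hurst_median`` may be a scalar or a per-channel sequence.
    """

    label: str
    n_subjects: int
    hurst_median: float | tuple[float, ...] = 0.7
    hurst_spread: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.hurst_spread < 0:
            raise ParameterError("hurst_spread must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group cohort of synthetic resting-state recordings.

    Defaults follow the study geometry scaled to desk size: 300 s at 400 Hz
    (generation directly at the post-downsample rate) with a handful of
    channels; the acquisition-scale 248-channel / 1017.25 Hz mode is reached
    simply by passing those values.
    """

    groups: tuple[GroupSpec, ...]
    duration: float = 300.0
    fs: float = 400.0
    n_channels: int = 4
    carrier_freq: float = 10.0
    snr: float = 10.0
    line_noise_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ParameterError("at least one group required")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("duration x fs must be integral")


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (exact circulant embedding)
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray | int, hurst: float,
                       variance: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance
    ``gamma(k) = (sigma^2/2) * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})``.
    """
    k = np.abs(np.atleast_1d(np.asarray(lags, dtype=np.float64)))
    h2 = 2.0 * hurst
    return 0.5 * variance * (
        np.abs(k + 1) ** h2 - 2.0 * k ** h2 + np.abs(k - 1) ** h2
    )


def _circulant_eigenvalues(n: int, hurst: float, variance: float) -> np.ndarray:
    """Eigenvalues of the smallest valid circulant embedding of the fGn
    covariance; doubles the embedding until non-negative definite."""
    m = n
    while True:
        g = fgn_autocovariance(np.arange(m + 1), hurst, variance)
        row = np.concatenate([g[:m], g[m:0:-1]])  # length 2m
        lam = np.fft.fft(row).real
        if lam.min() > -1e-8 * lam.max():
            return np.clip(lam, 0.0, None)
        if m > 2 ** 26:  # pragma: no cover - never reached for fGn
            raise RuntimeError("circulant embedding failed to become PSD")
        m *= 2


def gen_fgn(spec: FgnSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Exact sample of fractional Gaussian noise via circulant embedding.

    Returns a stationary Gaussian series of length ``spec.n_samples`` whose
    autocovariance is exactly ``fgn_autocovariance`` in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = _circulant_eigenvalues(spec.n_samples, spec.hurst, spec.variance)
    m2 = lam.size  # embedding size 2m
    z = rng.standard_normal(m2) + 1j * rng.standard_normal(m2)
    y = np.fft.fft(np.sqrt(lam / m2) * z)
    return np.ascontiguousarray(y.real[: spec.n_samples])


def gen_pink_noise(n_samples: int, fs: float,
                   rng: np.random.Generator,
                   f_floor: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f-power background via spectral synthesis.

    Spectral power falls as 1/f above ``f_floor`` and is flat below it
    (approximating the post-high-pass spectrum of resting MEG background).
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    amp[0] = 0.0
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phases, n=n_samples)
    sd = x.std()
    if sd == 0:  # pragma: no cover - n_samples >= 2 always gives variance
        raise DataError("degenerate pink-noise draw")
    return x / sd


# ---------------------------------------------------------------------------
# Modulated oscillations and recordings
# ---------------------------------------------------------------------------

def _modulated_components(
    spec: OscillationSpec, duration: float, fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(series, envelope)`` for one channel."""
    if spec.carrier_freq >= fs / 2:
        raise ParameterError(
            f"carrier {spec.carrier_freq} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    if duration < 10.0 / spec.carrier_freq:
        raise ParameterError("duration must cover at least 10 carrier cycles")
    n = int(round(duration * fs))

    # strictly positive envelope: shift-and-clip transform of unit-SD fGn
    z = gen_fgn(FgnSpec(spec.envelope_hurst, n), rng=rng)
    env = np.clip(1.0 + spec.mod_depth * z, 0.05, None)

    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    osc = env * np.cos(2.0 * np.pi * spec.carrier_freq * t + phase)

    if math.isinf(spec.snr):
        a, b = 1.0, 0.0
        bg = 0.0
    else:
        bg = gen_pink_noise(n, fs, rng)
        a = math.sqrt(spec.snr / (1.0 + spec.snr))
        b = math.sqrt(1.0 / (1.0 + spec.snr))
    osc_rms = np.sqrt(np.mean(osc ** 2))
    series = a * osc / osc_rms + b * bg
    if spec.line_noise_amp:
        series = series + spec.line_noise_amp * np.sin(2.0 * np.pi * 50.0 * t)
    # envelope returned on the scale actually mixed into the series
    return series, env * (a / osc_rms)


def gen_modulated_oscillation(spec: OscillationSpec, duration: float, fs: float,
                              seed: int = 0, *,
                              return_envelope: bool = False):
    """One channel of amplitude-modulated narrowband oscillation.

    The instantaneous amplitude is a shift-and-clip transform of exact fGn
    with Hurst exponent ``spec.envelope_hurst``, so the envelope's DFA
    exponent over windows of a second and longer approximates
    ``envelope_hurst``. Mixed with unit-variance 1/f background at power
    ratio ``snr`` and an optional 50 Hz line component.
    """
    rng = np.random.default_rng(seed)
    series, env = _modulated_components(spec, duration, fs, rng)
    return (series, env) if return_envelope else series


def layout_positions(n_channels: int) -> np.ndarray:
    """Deterministic unit-disc sensor layout (sunflower spiral).

    +y is anterior; the posterior half of the array is ``y < 0``.
    """
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def gen_recording(
    subject_params: OscillationSpec | list[OscillationSpec],
    n_channels: int = 4,
    duration: float = 300.0,
    fs: float = 400.0,
    seed: int = 0,
    mixing: np.ndarray | None = None,
) -> ContinuousRecording:
    """Multichannel recording; each channel is an independent modulated
    oscillation (optionally mixed across channels by ``mixing``).

    ``subject_params`` may be a single :class:`OscillationSpec` shared by all
    channels or one spec per channel (e.g. per-channel envelope Hurst
    exponents).
    """
    if n_channels < 1:
        raise ParameterError("n_channels must be >= 1")
    if isinstance(subject_params, OscillationSpec):
        specs = [subject_params] * n_channels
    else:
        specs = list(subject_params)
        if len(specs) != n_channels:
            raise ParameterError(
                f"{len(specs)} channel specs for {n_channels} channels"
            )
    children = np.random.SeedSequence(seed).spawn(n_channels)
    n = int(round(duration * fs))
    data = np.empty((n_channels, n))
    for c, (sp, ss) in enumerate(zip(specs, children)):
        data[c], _ = _modulated_components(sp, duration, fs,
                                           np.random.default_rng(ss))
    if mixing is not None:
        mixing = np.asarray(mixing, dtype=np.float64)
        if mixing.shape != (n_channels, n_channels):
            raise ParameterError("mixing must be (n_channels, n_channels)")
        data = mixing @ data
    prov = {
        "op": "gen_recording",
        "generative_model": "stand-in",
        "seed": int(seed),
        "n_channels": n_channels,
        "duration": duration,
        "fs": fs,
        "channel_specs": [vars(s) | {} for s in specs],
    }
    return ContinuousRecording(
        data=data,
        fs=fs,
        channel_names=[f"CH{c + 1:03d}" for c in range(n_channels)],
        channel_pos=layout_positions(n_channels),
        provenance=[prov],
    )


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(
    rec: ContinuousRecording, spec: ArtifactSpec, seed: int = 0,
) -> tuple[ContinuousRecording, ArtifactAnnotations]:
    """Add step discontinuities and broadband bursts at Poisson-drawn times.

    Jumps emulate SQUID baseline steps: a persistent offset of
    ``jump_amplitude`` channel SDs added to one channel from the event sample
    onward (annotated at the discontinuity itself). Bursts add broadband
    noise of ``burst_gain`` channel SDs to all channels over
    ``burst_duration`` seconds. Returns the modified recording and the exact
    sample intervals of every injected event; overlapping events are merged
    with a warning.
    """
    if rec.n_samples == 0:
        raise DataError("empty recording")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n = rec.n_samples
    minutes = rec.duration / 60.0
    sd = data.std(axis=1)

    intervals: list[tuple[int, int]] = []
    kinds: list[str] = []

    n_jumps = rng.poisson(spec.jump_rate * minutes)
    for _ in range(n_jumps):
        s = int(rng.integers(1, n - 1))
        ch = int(rng.integers(0, rec.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[ch, s:] += sign * spec.jump_amplitude * sd[ch]
        intervals.append((s, s + 1))
        kinds.append("jump")

    n_bursts = rng.poisson(spec.burst_rate * minutes)
    blen = max(int(round(spec.burst_duration * rec.fs)), 1)
    for _ in range(n_bursts):
        s = int(rng.integers(0, max(n - blen, 1)))
        e = min(s + blen, n)
        data[:, s:e] += (
            rng.standard_normal((rec.n_channels, e - s))
            * (spec.burst_gain * sd)[:, None]
        )
        intervals.append((s, e))
        kinds.append("burst")

    if not intervals:
        ann = ArtifactAnnotations(np.empty((0, 2), dtype=np.int64), [])
        return rec.copy(), ann

    ann = ArtifactAnnotations(np.array(intervals, dtype=np.int64), kinds)
    merged = ann.normalized()
    raw_total = int(np.sum(ann.intervals[:, 1] - ann.intervals[:, 0]))
    if int(merged.to_mask(n).sum()) < raw_total:
        warnings.warn("overlapping artifact events merged", stacklevel=2)
    out = rec.with_data(data, step={
        "op": "inject_artifacts", "seed": int(seed), "spec": vars(spec) | {},
        "n_jumps": int(n_jumps), "n_bursts": int(n_bursts),
    })
    return out, merged


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecording:
    subject_id: str
    group: str
    recording: ContinuousRecording
    true_hurst: np.ndarray  # per-channel envelope Hurst exponents


@dataclass
class Cohort:
    subjects: list[SubjectRecording]
    spec: CohortSpec
    provenance: dict = field(default_factory=dict)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def true_delta_median(self, group: str, reference: str) -> float:
        """Difference of the *generating* group Hurst medians (scalar
        summary: mean over channels)."""
        by_label = {g.label: g for g in self.spec.groups}
        a = float(np.mean(by_label[group].hurst_median))
        b = float(np.mean(by_label[reference].hurst_median))
        return a - b


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Cohort of labelled recordings with per-subject Hurst ground truth.

    Each subject's channel-wise envelope Hurst exponents are the group's
    stated (per-channel) median plus a subject-level N(0, spread^2) offset,
    clipped to [0.05, 0.95]; the true group difference is recoverable from
    provenance. With one subject per group, downstream between-subject
    resampling intervals are undefined — generation itself still works.
    """
    subjects: list[SubjectRecording] = []
    prov: dict = {"op": "gen_cohort", "generative_model": "stand-in",
                  "seed": spec.seed, "groups": {}, "subject_hurst": {}}
    for g_idx, group in enumerate(spec.groups):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g_idx]))
        medians = np.broadcast_to(
            np.asarray(group.hurst_median, dtype=np.float64),
            (spec.n_channels,),
        ) if np.ndim(group.hurst_median) else np.full(
            spec.n_channels, float(group.hurst_median))
        prov["groups"][group.label] = {
            "n_subjects": group.n_subjects,
            "hurst_median": [float(m) for m in medians],
            "hurst_spread": group.hurst_spread,
        }
        for s_idx in range(group.n_subjects):
            offset = rng.normal(0.0, group.hurst_spread)
            hvec = np.clip(medians + offset, 0.05, 0.95)
            sid = f"{group.label}-{s_idx + 1:03d}"
            sub_seed = int(
                np.random.SeedSequence([spec.seed, g_idx, s_idx]).generate_state(1)[0]
                % (2 ** 31)
            )
            chans = [
                OscillationSpec(
                    carrier_freq=spec.carrier_freq,
                    envelope_hurst=float(h),
                    snr=spec.snr,
                    line_noise_amp=spec.line_noise_amp,
                )
                for h in hvec
            ]
            rec = gen_recording(chans, spec.n_channels, spec.duration,
                                spec.fs, seed=sub_seed)
            rec.provenance[0]["subject_id"] = sid
            rec.provenance[0]["group"] = group.label
            rec.provenance[0]["true_hurst"] = [float(h) for h in hvec]
            prov["subject_hurst"][sid] = [float(h) for h in hvec]
            subjects.append(SubjectRecording(sid, group.label, rec, hvec))
    return Cohort(subjects=subjects, spec=spec, provenance=prov)
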