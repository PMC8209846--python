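"""In-memory containers for continuous recordings and artifact annotations.

Conventions used throughout the package:

* data arrays are ``channels x samples`` float64;
* sample intervals are 0-based and half-open, ``[start, stop)``;
* every processing stage appends a dict to ``provenance`` describing the
  operation and its parameters, so a run can be audited or replayed.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError

__all__ = ["ContinuousRecording", "ArtifactAnnotations", "ComponentModel"]


@dataclass
class ContinuousRecording:
    """A continuous multichannel electrophysiological recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in native units (tesla for MEG, volts for EEG — the pipeline
        is unit-agnostic).
    fs : float
        Sampling frequency in Hz.
    channel_names : list of str
        Unique channel labels.
    channel_pos : ndarray, shape (n_channels, 2), optional
        Flattened 2-D sensor-layout coordinates; the convention is a unit
        disc with +y anterior, so "posterior" channels have negative (or
        below-median) y.
    provenance : list of dict
        Ordered processing history. Generators record their full
        specification (including seeds) here.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_pos: np.ndarray | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise DataError("channel names must be unique")
        if self.channel_pos is not None:
            self.channel_pos = np.asarray(self.channel_pos, dtype=np.float64)
            if self.channel_pos.shape != (self.data.shape[0], 2):
                raise DataError("channel_pos must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_pos=None if self.channel_pos is None else self.channel_pos.copy(),
            provenance=_copy.deepcopy(self.provenance),
        )

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  step: dict | None = None) -> "ContinuousRecording":
        """Return a new recording with replaced data and appended provenance."""
        rec = ContinuousRecording(
            data=np.asarray(data, dtype=np.float64),
            fs=self.fs if fs is None else float(fs),
            channel_names=list(self.channel_names),
            channel_pos=None if self.channel_pos is None else self.channel_pos.copy(),
            provenance=_copy.deepcopy(self.provenance),
        )
        if step is not None:
            rec.provenance.append(step)
        return rec


VALID_KINDS = ("replace", "reject_channel", "artifact_ic", "jump", "burst")


@dataclass
class ArtifactAnnotations:
    """Sample-indexed artifact intervals, half-open ``[start, stop)``.

    ``kinds`` labels each interval; ``jump``/``burst`` are ground-truth
    labels written by the synthetic generator, ``replace`` marks segments
    for reconstruction.
    """

    intervals: np.ndarray  # (n, 2) int64
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if not self.kinds:
            self.kinds = ["replace"] * len(self.intervals)
        if len(self.kinds) != len(self.intervals):
            raise DataError("one kind per interval required")
        for k in self.kinds:
            if k not in VALID_KINDS:
                raise ParameterError(f"unknown annotation kind {k!r}")
        if np.any(self.intervals[:, 0] >= self.intervals[:, 1]):
            raise DataError("annotation intervals require start < stop")

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_bounds(self, n_samples: int) -> None:
        if len(self) and (
            self.intervals.min() < 0 or self.intervals.max() > n_samples
        ):
            raise DataError("annotation interval outside recording bounds")

    def normalized(self) -> "ArtifactAnnotations":
        """Sort intervals and merge overlapping/touching ones of equal kind."""
        if len(self) == 0:
            return ArtifactAnnotations(np.empty((0, 2), dtype=np.int64), [])
        order = np.lexsort((self.intervals[:, 1], self.intervals[:, 0]))
        merged: list[list[int]] = []
        kinds: list[str] = []
        for i in order:
            s, e = self.intervals[i]
            k = self.kinds[i]
            if merged and kinds[-1] == k and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
                kinds.append(k)
        return ArtifactAnnotations(np.array(merged, dtype=np.int64), kinds)

    def to_mask(self, n_samples: int, kinds: tuple[str, ...] | None = None) -> np.ndarray:
        """Boolean sample mask, True inside annotated intervals."""
        mask = np.zeros(n_samples, dtype=bool)
        for (s, e), k in zip(self.intervals, self.kinds):
            if kinds is None or k in kinds:
                mask[max(int(s), 0):min(int(e), n_samples)] = True
        return mask

    def total_samples(self, kinds: tuple[str, ...] | None = None) -> int:
        return int(self.to_mask(int(self.intervals.max()) if len(self) else 0,
                                kinds).sum()) if len(self) else 0


@dataclass
class ComponentModel:
    """A stored linear decomposition applied to continuous data.

    Only the *application* of an existing unmixing/mixing pair (e.g. from an
    ICA fitted elsewhere) is supported; fitting is out of scope.
    """

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray    # channels x components
    bad_components: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.unmixing = np.asarray(self.unmixing, dtype=np.float64)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.unmixing.ndim != 2 or self.mixing.ndim != 2:
            raise DataError("unmixing and mixing must be 2-D")
        if self.mixing.shape != self.unmixing.shape[::-1]:
            raise DataError(
                f"mixing shape {self.mixing.shape} incompatible with "
                f"unmixing shape {self.unmixing.shape}"
            )
        n_comp = self.unmixing.shape[0]
        if any(not 0 <= c < n_comp for c in self.bad_components):
            raise ParameterError("bad_components index out of range")
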