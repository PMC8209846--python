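"""HDF5 container layouts, configuration parsing, and tabular exports.

Recording layout (format_version 1.0): datasets ``/data`` (channels x
samples), ``/fs``, ``/channel_names``, ``/channel_pos`` (optional),
``/provenance`` (JSON string), ``/annotations`` (optional table of start,
stop, kind). Exponent-map layout: ``/alpha``, ``/r2``, ``/n_windows``,
``/frequencies``, ``/channels``, ``/channel_pos`` (optional).

Readers verify ``format_version`` and reject newer majors; a missing
required dataset raises :class:`~lrtcpipe.errors.SchemaError` naming the
field. Configuration files are YAML with strict validation: unknown keys
are rejected, and defaults equal the standard analysis parameters (49-51 Hz
order-3 notch; 1 Hz order-3052 high-pass; 400 Hz; bank 4-40 Hz n=40; grid
0.08-300 s n=181; fit 1-60 s; 5000 resamples).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .containers import ArtifactAnnotations, ContinuousRecording
from .dfa import ScalingExponentMap
from .errors import ConfigError, SchemaError

__all__ = [
    "FORMAT_VERSION",
    "write_recording",
    "read_recording",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "write_exponent_map",
    "read_exponent_map",
    "exponent_map_to_frame",
    "SimulateConfig",
    "PreprocessStageConfig",
    "DfaConfig",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
]

FORMAT_VERSION = "1.0"


def _check_version(h5: h5py.File, path: str) -> None:
    ver = h5.attrs.get("format_version")
    if ver is None:
        raise SchemaError(f"{path}: missing format_version attribute")
    major = str(ver).split(".")[0]
    if int(major) > int(FORMAT_VERSION.split(".")[0]):
        raise SchemaError(
            f"{path}: format_version {ver} newer than supported "
            f"{FORMAT_VERSION}"
        )


def _require(h5: h5py.File, name: str, path: str):
    if name not in h5:
        raise SchemaError(f"{path}: missing required dataset /{name}")
    return h5[name]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def write_recording(rec: ContinuousRecording, path: str | Path,
                    annotations: ArtifactAnnotations | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.create_dataset("data", data=rec.data)
        h5.create_dataset("fs", data=float(rec.fs))
        h5.create_dataset("channel_names",
                          data=np.array(rec.channel_names, dtype="S"))
        if rec.channel_pos is not None:
            h5.create_dataset("channel_pos", data=rec.channel_pos)
        h5.create_dataset("provenance",
                          data=json.dumps(rec.provenance, default=str))
        if annotations is not None and len(annotations):
            grp = h5.create_group("annotations")
            grp.create_dataset("intervals", data=annotations.intervals)
            grp.create_dataset("kinds",
                               data=np.array(annotations.kinds, dtype="S"))


def read_recording(path: str | Path,
                   ) -> tuple[ContinuousRecording, ArtifactAnnotations | None]:
    path = str(path)
    with h5py.File(path, "r") as h5:
        _check_version(h5, path)
        data = _require(h5, "data", path)[()]
        fs = float(_require(h5, "fs", path)[()])
        names = [n.decode() for n in _require(h5, "channel_names", path)[()]]
        pos = h5["channel_pos"][()] if "channel_pos" in h5 else None
        prov = json.loads(_require(h5, "provenance", path)[()])
        ann = None
        if "annotations" in h5:
            ann = ArtifactAnnotations(
                h5["annotations/intervals"][()],
                [k.decode() for k in h5["annotations/kinds"][()]],
            )
    rec = ContinuousRecording(data=data, fs=fs, channel_names=names,
                              channel_pos=pos, provenance=prov)
    return rec, ann


def write_annotations_tsv(ann: ArtifactAnnotations, fs: float,
                          path: str | Path) -> None:
    """Sidecar export: start_s, stop_s, kind (tab-separated)."""
    df = pd.DataFrame({
        "start_s": ann.intervals[:, 0] / fs,
        "stop_s": ann.intervals[:, 1] / fs,
        "kind": ann.kinds,
    })
    df.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str | Path, fs: float) -> ArtifactAnnotations:
    df = pd.read_csv(path, sep="\t")
    iv = np.column_stack([
        np.round(df["start_s"].to_numpy() * fs).astype(np.int64),
        np.round(df["stop_s"].to_numpy() * fs).astype(np.int64),
    ])
    return ArtifactAnnotations(iv, list(df["kind"]))


def import_foreign(path: str | Path) -> ContinuousRecording:
    """Optional adapter for vendor MEG/EEG formats via mne.

    Requires ``mne`` (an optional dependency): reads any format
    ``mne.io.read_raw`` understands and converts it to a
    :class:`ContinuousRecording` (2-D layout positions taken from the first
    two device-coordinate components where available). Degrades gracefully
    when mne is absent.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne present in CI env
        raise DataError(
            "foreign-format import requires the optional 'mne' dependency; "
            "install mne or convert the file to the project HDF5 layout"
        ) from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    return from_mne_raw(raw)


def from_mne_raw(raw) -> ContinuousRecording:
    """Convert an in-memory ``mne.io.Raw`` object to a ContinuousRecording."""
    data = raw.get_data()
    pos = None
    try:
        locs = np.array([ch["loc"][:2] for ch in raw.info["chs"]])
        if np.isfinite(locs).all() and np.ptp(locs) > 0:
            pos = locs
    except Exception:
        pos = None
    return ContinuousRecording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names), channel_pos=pos,
        provenance=[{"op": "import_foreign", "source": "mne"}],
    )


# ---------------------------------------------------------------------------
# Exponent maps
# ---------------------------------------------------------------------------

def write_exponent_map(m: ScalingExponentMap, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["method"] = m.method
        h5.create_dataset("alpha", data=m.alpha)
        h5.create_dataset("r2", data=m.fit_r2)
        h5.create_dataset("n_windows", data=m.n_windows_used)
        h5.create_dataset("frequencies", data=m.frequencies)
        h5.create_dataset("channels",
                          data=np.array(m.channel_names, dtype="S"))
        if m.channel_pos is not None:
            h5.create_dataset("channel_pos", data=m.channel_pos)


def read_exponent_map(path: str | Path) -> ScalingExponentMap:
    path = str(path)
    with h5py.File(path, "r") as h5:
        _check_version(h5, path)
        return ScalingExponentMap(
            alpha=_require(h5, "alpha", path)[()],
            fit_r2=_require(h5, "r2", path)[()],
            n_windows_used=h5["n_windows"][()] if "n_windows" in h5 else
            np.zeros_like(h5["alpha"][()], dtype=np.int64),
            frequencies=_require(h5, "frequencies", path)[()],
            channel_names=[c.decode() for c in
                           _require(h5, "channels", path)[()]],
            method=str(h5.attrs.get("method", "fourier")),
            channel_pos=h5["channel_pos"][()] if "channel_pos" in h5 else None,
        )


def exponent_map_to_frame(m: ScalingExponentMap,
                          subject_id: str = "") -> pd.DataFrame:
    """Long-format export: subject, channel, freq_hz, alpha, r2, method."""
    nc, nf = m.alpha.shape
    return pd.DataFrame({
        "subject": np.repeat(subject_id, nc * nf),
        "channel": np.repeat(m.channel_names, nf),
        "freq_hz": np.tile(m.frequencies, nc),
        "alpha": m.alpha.ravel(),
        "r2": m.fit_r2.ravel(),
        "method": m.method,
    })


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_StrictModel):
    groups: list[dict] = [
        {"label": "CTRL", "n_subjects": 2, "hurst_median": 0.7,
         "hurst_spread": 0.05},
        {"label": "CLIN", "n_subjects": 2, "hurst_median": 0.75,
         "hurst_spread": 0.05},
    ]
    duration: float = 300.0
    fs: float = 400.0
    n_channels: int = 4
    carrier_freq: float = 10.0
    snr: float = 10.0
    line_noise_amp: float = 0.0
    jump_rate: float = 0.0
    burst_rate: float = 0.0


class PreprocessStageConfig(_StrictModel):
    bad_channels: list[str] = []
    demean: bool = True
    notch_low: float | None = 49.0
    notch_high: float | None = 51.0
    notch_order: int = 3
    highpass_cutoff: float | None = 1.0
    highpass_order: int = 3052
    target_fs: float | None = 400.0
    detect_z_thresh: float | None = 8.0
    replace_mode: str = "mirror"
    sg_order: int = 1
    sg_frame: int = 41
    max_gap: float = 4.0


class DfaConfig(_StrictModel):
    method: str = "fourier"
    f_min: float = 4.0
    f_max: float = 40.0
    n_freqs: int = 40
    n_cycles: float = 2.0
    grid_t_min: float = 0.08
    grid_t_max: float = 300.0
    grid_n: int = 181
    fit_t_min: float = 1.0
    fit_t_max: float = 60.0
    kernel_const: float | None = None  # None = package calibration constant


class StatsConfig(_StrictModel):
    control_label: str = "CTRL"
    n_permutations: int = 5000
    n_bootstrap: int = 5000
    statistic: str = "median_diff"
    channel_subset: str = "all"  # "all" | "posterior"
    bonferroni: bool = False


class PipelineConfig(_StrictModel):
    master_seed: int = 0
    out_dir: str = "lrtcpipe_out"
    simulate: SimulateConfig = SimulateConfig()
    preprocess: PreprocessStageConfig = PreprocessStageConfig()
    dfa: DfaConfig = DfaConfig()
    stats: StatsConfig = StatsConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and strictly validate a YAML pipeline configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc
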