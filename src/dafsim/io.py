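"""File formats: WAV audio, CSV annotations, JSON-lines event logs, YAML config.

Conventions: all audio is mono (stereo is an error, never a silent
downmix), PCM-16 or IEEE float, normalized to [-1, 1] on read.  Event
logs are append-only JSON lines carrying times both in samples (exact,
authoritative) and seconds (convenience).  Config files mirror the
dataclass field names exactly; unknown keys are errors, not warnings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .engine import DetectionEvent, EngineConfig, ModeChangeEvent
from .exceptions import ChannelError, ConfigurationError, FormatError, ValidationError
from .feedback import FeedbackPolicy, PlaybackEvent
from .spectral import SpectralParams
from .synth import Annotation

__all__ = [
    "read_wav", "write_wav",
    "read_annotations", "write_annotations",
    "write_event_log", "read_event_log", "events_to_records",
    "load_config", "config_hash",
]


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono WAV; returns (samples in [-1, 1] float64, sample rate)."""
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as e:
        raise FormatError(f"cannot read WAV {path}: {e}") from e
    if data.ndim != 1:
        raise ChannelError(
            f"{path} has {data.shape[1]} channels; mono required (no silent downmix)")
    if data.dtype in _PCM_SCALE:
        return data.astype(np.float64) / _PCM_SCALE[data.dtype], int(rate)
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float64), int(rate)
    raise FormatError(f"{path}: unsupported WAV encoding {data.dtype}")


def write_wav(path: str | Path, samples: np.ndarray, rate: int,
              encoding: str = "float32") -> None:
    """Write mono WAV; ``encoding`` is "float32", "float64" or "pcm16"."""
    samples = np.asarray(samples)
    if samples.ndim != 1:
        raise ChannelError("only mono output is supported")
    if encoding == "float32":
        wavfile.write(str(path), int(rate), samples.astype(np.float32))
    elif encoding == "float64":
        wavfile.write(str(path), int(rate), samples.astype(np.float64))
    elif encoding == "pcm16":
        quantized = np.clip(np.round(samples * 32768.0), -32768, 32767)
        wavfile.write(str(path), int(rate), quantized.astype(np.int16))
    else:
        raise FormatError(f"unknown encoding {encoding!r}")


# ---------------------------------------------------------------------------
# Annotations (CSV: label,onset_s,offset_s[,f0_hz])
# ---------------------------------------------------------------------------

def write_annotations(path: str | Path, annotations: list[Annotation]) -> None:
    df = pd.DataFrame([{"label": a.label, "onset_s": a.onset_s,
                        "offset_s": a.offset_s, "f0_hz": a.f0_hz}
                       for a in annotations],
                      columns=["label", "onset_s", "offset_s", "f0_hz"])
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read and validate an annotation CSV.

    Intervals must be well-formed (onset < offset), time-ordered and
    non-overlapping; errors name the offending file line (header is
    line 1).
    """
    df = pd.read_csv(path)
    required = {"label", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: annotation CSV needs columns {sorted(required)}")
    out: list[Annotation] = []
    prev_offset = -np.inf
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if not onset < offset:
            raise ValidationError(
                f"{path} line {line}: offset {offset} not after onset {onset}")
        if onset < prev_offset:
            raise ValidationError(
                f"{path} line {line}: interval overlaps or precedes the previous one")
        prev_offset = offset
        f0 = float(row["f0_hz"]) if "f0_hz" in df.columns else float("nan")
        out.append(Annotation(label=str(row["label"]), onset_s=onset,
                              offset_s=offset, f0_hz=f0))
    return out


# ---------------------------------------------------------------------------
# Event log (JSON lines)
# ---------------------------------------------------------------------------

def events_to_records(events: list, sample_rate_hz: float) -> list[dict]:
    """Convert engine/feedback events to JSON-serializable records."""
    records = []
    for ev in events:
        if isinstance(ev, DetectionEvent):
            records.append({"type": "detection", "time_samples": int(ev.time),
                            "time_s": ev.time / sample_rate_hz,
                            "template_id": ev.template_id,
                            "correlation": float(ev.correlation)})
        elif isinstance(ev, ModeChangeEvent):
            records.append({"type": "mode_change", "time_samples": int(ev.time),
                            "time_s": ev.time / sample_rate_hz,
                            "mode": ev.mode, "rms": float(ev.rms)})
        elif isinstance(ev, PlaybackEvent):
            records.append({"type": "playback", "time_samples": int(ev.start),
                            "time_s": ev.start / sample_rate_hz,
                            "end_samples": int(ev.end),
                            "template_id": ev.cause.template_id,
                            "cause_time_samples": int(ev.cause.time)})
        else:
            raise TypeError(f"cannot serialize event of type {type(ev).__name__}")
    records.sort(key=lambda r: r["time_samples"])
    return records


def write_event_log(path: str | Path, events: list, sample_rate_hz: float,
                    header: dict | None = None) -> None:
    with open(path, "w") as fh:
        if header is not None:
            fh.write(json.dumps({"type": "header", **header}) + "\n")
        for rec in events_to_records(events, sample_rate_hz):
            fh.write(json.dumps(rec) + "\n")


def read_event_log(path: str | Path) -> list[dict]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


# ---------------------------------------------------------------------------
# Config (YAML mirroring the dataclass field names)
# ---------------------------------------------------------------------------

_SPECTRAL_KEYS = {"sample_rate_hz", "fft_size", "hop_ms", "taper",
                  "magnitude_scale", "band_hz"}
_ENGINE_KEYS = {"gate_rms_threshold", "gate_window_ms", "gate_check_every_ms",
                "idle_return_rms_threshold", "idle_return_window_ms",
                "idle_return_check_every_s", "refractory_ms", "record_triggered",
                "sample_ring_capacity", "spectro_ring_capacity"}
_FEEDBACK_KEYS = {"mode", "probability", "delay_ms", "pitch_threshold_hz",
                  "direction", "sound", "sound_duration_ms", "amplitude",
                  "noise_kind", "pitch_window_ms"}


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {name} config: {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    """Load a YAML run config with sections ``spectral``, ``engine``,
    ``feedback`` (all optional).  Unknown keys in any section are errors.

    Returns ``{"spectral": SpectralParams, "engine": dict, "feedback":
    FeedbackPolicy | None, "seed": int | None}``; the engine dict holds
    keyword arguments for :class:`EngineConfig` (templates are attached
    by the caller).
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys(doc, {"spectral", "engine", "feedback", "seed"}, "top-level")
    spectral_d = doc.get("spectral", {}) or {}
    _check_keys(spectral_d, _SPECTRAL_KEYS, "spectral")
    if "band_hz" in spectral_d and spectral_d["band_hz"] is not None:
        spectral_d["band_hz"] = tuple(spectral_d["band_hz"])
    spectral = SpectralParams(**spectral_d)
    engine_d = doc.get("engine", {}) or {}
    _check_keys(engine_d, _ENGINE_KEYS, "engine")
    feedback = None
    if "feedback" in doc and doc["feedback"]:
        fd = dict(doc["feedback"])
        _check_keys(fd, _FEEDBACK_KEYS, "feedback")
        if "pitch_window_ms" in fd:
            fd["pitch_window_ms"] = tuple(fd["pitch_window_ms"])
        feedback = FeedbackPolicy(**fd)
    return {"spectral": spectral, "engine": engine_d, "feedback": feedback,
            "seed": doc.get("seed")}


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable config representation."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
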