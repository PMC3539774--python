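"""Streaming detection engine: the two-mode state machine.

The engine consumes one sample at a time and mimics the behavior of a
real-time acoustic feedback rig, causally:

* **idle mode** — every gate-check period (1 ms) the rms of the last
  10 ms of input is compared against a threshold; a crossing switches
  the engine to triggered mode.
* **triggered mode** — every hop (1 ms) a new FFT magnitude column is
  pushed into the spectrogram ring and each template is correlated
  against the most recent same-shape patch; a correlation at or above
  the template's threshold, outside lockout and refractory, emits a
  :class:`DetectionEvent` timed at the last sample of the matched
  window.  Every second, the rms of the previous 200 ms is checked and
  the engine returns to idle when the sound has stopped, closing the
  recorded :class:`TriggerSegment`.

All timing is integer sample arithmetic on a global grid (check periods
divide the running sample count), so the event log is bit-identical no
matter how the stream is chunked, and truncating the stream never
changes events already emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .buffers import SampleRing, SpectroRing
from .exceptions import ConfigurationError, DegenerateInputError, RangeError
from .spectral import SpectralParams, Template, fft_magnitude, spectrogram_correlation

__all__ = [
    "EngineConfig",
    "Engine",
    "DetectionEvent",
    "ModeChangeEvent",
    "TriggerSegment",
    "rms",
    "run_stream",
]


def rms(window: np.ndarray) -> float:
    """Root-mean-square amplitude of a window; RangeError on empty input."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise RangeError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(window * window)))


@dataclass(frozen=True)
class DetectionEvent:
    """A template crossing its correlation threshold.

    ``time`` is the sample index of the last sample of the matched
    window — the detection time, which by template construction falls
    inside the target syllable.
    """
    template_id: str
    time: int
    correlation: float


@dataclass(frozen=True)
class ModeChangeEvent:
    time: int
    mode: str          # mode entered: "triggered" or "idle"
    rms: float         # gate rms that caused the transition


@dataclass
class TriggerSegment:
    """Audio recorded between a trigger and the return to idle."""
    start: int
    end: int
    samples: np.ndarray
    events: list[DetectionEvent] = field(default_factory=list)


@dataclass
class EngineConfig:
    """Engine parameters.

    Gate thresholds carry no canonical values; calibrate them from a
    noise-floor segment with :meth:`calibrated` (trigger at 3x the noise
    rms, idle-return at 1.5x — the hysteresis prevents oscillation).
    ``refractory_ms`` defaults to one full template span per template so
    a single syllable rendition yields a single detection.
    """
    spectral: SpectralParams
    templates: list[Template] = field(default_factory=list)
    gate_rms_threshold: float = 0.02
    gate_window_ms: float = 10.0
    gate_check_every_ms: float = 1.0
    idle_return_rms_threshold: float = 0.01
    idle_return_window_ms: float = 200.0
    idle_return_check_every_s: float = 1.0
    refractory_ms: float | None = None
    record_triggered: bool = True
    sample_ring_capacity: int | None = None   # default: 2 s of audio
    spectro_ring_capacity: int = 512

    def __post_init__(self):
        for name in ("gate_window_ms", "gate_check_every_ms",
                     "idle_return_window_ms", "idle_return_check_every_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.gate_rms_threshold < 0 or self.idle_return_rms_threshold < 0:
            raise ConfigurationError("rms thresholds must be >= 0")
        if self.refractory_ms is not None and self.refractory_ms < 0:
            raise ConfigurationError("refractory_ms must be >= 0")

    @classmethod
    def calibrated(cls, noise_segment: np.ndarray, spectral: SpectralParams,
                   templates: list[Template] | None = None,
                   trigger_factor: float = 3.0, idle_factor: float = 1.5,
                   **kwargs) -> "EngineConfig":
        """Set gate thresholds relative to the rms of a noise-floor segment."""
        base = rms(noise_segment)
        return cls(spectral=spectral, templates=list(templates or []),
                   gate_rms_threshold=trigger_factor * base,
                   idle_return_rms_threshold=idle_factor * base, **kwargs)

    def refractory_samples(self, template: Template) -> int:
        if self.refractory_ms is not None:
            return self.spectral.ms_to_samples(self.refractory_ms)
        span = template.pre_roll_ms + template.duration_ms
        return self.spectral.ms_to_samples(span)


class Engine:
    """Causal, sample-by-sample simulation of the detection loop.

    ``step`` consumes one sample; ``process`` consumes a chunk and is
    bit-identical to calling ``step`` per sample (all state changes
    happen on the global check grid).  ``finish`` closes any open
    trigger segment at end-of-stream.
    """

    def __init__(self, config: EngineConfig):
        if config.spectral is None:
            raise ConfigurationError("engine requires spectral parameters")
        self.config = config
        sp = config.spectral
        self.hop = sp.hop
        self.gate_check = sp.ms_to_samples(config.gate_check_every_ms)
        self.gate_window = sp.ms_to_samples(config.gate_window_ms)
        self.idle_check = sp.ms_to_samples(config.idle_return_check_every_s * 1000.0)
        self.idle_window = sp.ms_to_samples(config.idle_return_window_ms)
        cap = config.sample_ring_capacity or max(
            2 * round(sp.sample_rate_hz), self.idle_window, sp.fft_size)
        self.ring = SampleRing(cap)
        self.spectro = SpectroRing(config.spectro_ring_capacity, sp.n_bins)
        self.templates = sorted(config.templates, key=lambda t: t.id)
        for t in self.templates:
            if t.params.n_bins != sp.n_bins:
                raise ConfigurationError(
                    f"template {t.id!r} bin count differs from engine spectral params")
        self.mode = "idle"
        self.lockout_until = 0      # no detection at t < lockout_until
        self.refractory_until = {t.id: 0 for t in self.templates}
        self.segments: list[TriggerSegment] = []
        self._seg_start = 0
        self._seg_chunks: list[np.ndarray] = []
        self._seg_events: list[DetectionEvent] = []

    # -- internal ----------------------------------------------------------

    def _next_boundary(self, total: int) -> int:
        """Smallest sample index t >= total where a check is due."""
        periods = ([self.gate_check] if self.mode == "idle"
                   else [self.hop, self.idle_check])
        return min(-(-(total + 1) // p) * p - 1 for p in periods)

    def _close_segment(self, end: int) -> None:
        samples = (np.concatenate(self._seg_chunks)
                   if self._seg_chunks else np.zeros(0))
        self.segments.append(TriggerSegment(
            start=self._seg_start, end=end, samples=samples,
            events=self._seg_events))
        self._seg_chunks = []
        self._seg_events = []

    def _boundary(self, t: int) -> list:
        events = []
        cfg = self.config
        if self.mode == "idle":
            if (t + 1) % self.gate_check == 0 and self.ring.total_pushed >= self.gate_window:
                level = rms(self.ring.latest_window(self.gate_window))
                if level > cfg.gate_rms_threshold:
                    self.mode = "triggered"
                    self.spectro.clear()
                    self._seg_start = max(0, t + 1 - self.gate_window)
                    take = min(self.gate_window, len(self.ring))
                    self._seg_chunks = [self.ring.latest_window(take)]
                    self._seg_events = []
                    events.append(ModeChangeEvent(time=t, mode="triggered", rms=level))
        if self.mode == "triggered":
            if (t + 1) % self.hop == 0 and self.ring.total_pushed >= cfg.spectral.fft_size:
                col = fft_magnitude(self.ring.latest_window(cfg.spectral.fft_size),
                                    cfg.spectral)
                self.spectro.push(col, t)
                for tmpl in self.templates:
                    k = tmpl.n_cols
                    if len(self.spectro) < k:
                        continue
                    if t < self.lockout_until or t < self.refractory_until[tmpl.id]:
                        continue
                    patch = self.spectro.latest_spectrogram(k)
                    try:
                        r = spectrogram_correlation(
                            patch, tmpl.patch, band_hz=cfg.spectral.band_hz,
                            params=cfg.spectral)
                    except DegenerateInputError:
                        continue
                    if r >= tmpl.threshold:
                        det = DetectionEvent(template_id=tmpl.id, time=t, correlation=r)
                        events.append(det)
                        self._seg_events.append(det)
                        self.refractory_until[tmpl.id] = t + self.config.refractory_samples(tmpl)
            if (t + 1) % self.idle_check == 0 and self.ring.total_pushed >= self.idle_window:
                level = rms(self.ring.latest_window(self.idle_window))
                if level < cfg.idle_return_rms_threshold:
                    self._close_segment(end=t)
                    self.mode = "idle"
                    events.append(ModeChangeEvent(time=t, mode="idle", rms=level))
        return events

    # -- public ------------------------------------------------------------

    def process(self, chunk: np.ndarray) -> list:
        """Feed a chunk of samples; returns events in order of occurrence."""
        chunk = np.asarray(chunk, dtype=np.float64)
        events: list = []
        i, n = 0, chunk.size
        while i < n:
            total = self.ring.total_pushed
            nb = self._next_boundary(total)
            take = min(nb + 1 - total, n - i)
            part = chunk[i:i + take]
            self.ring.extend(part)
            if self.mode == "triggered" and self.config.record_triggered:
                self._seg_chunks.append(part.copy())
            i += take
            if self.ring.total_pushed - 1 == nb:
                events.extend(self._boundary(nb))
        return events

    def step(self, sample: float) -> list:
        """Feed a single sample (identical semantics to ``process([sample])``)."""
        return self.process(np.array([sample], dtype=np.float64))

    def finish(self) -> None:
        """Close any open trigger segment at end-of-stream."""
        if self.mode == "triggered":
            self._close_segment(end=self.ring.total_pushed - 1)
            self.mode = "idle"


def run_stream(samples: np.ndarray, config: EngineConfig,
               ) -> tuple[list, list[TriggerSegment]]:
    """Run the engine over a whole recording.

    Identical to feeding every sample through :meth:`Engine.step`; the
    final open segment is closed at end-of-stream.  Returns the event
    log and the recorded trigger segments.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise RangeError("cannot run the engine on an empty stream")
    eng = Engine(config)
    events = eng.process(samples)
    eng.finish()
    return events, eng.segments
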