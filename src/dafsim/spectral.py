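"""Short-time spectral analysis and spectrogram-template matching.

The detector correlates the spectrogram of the most recent stretch of
audio against the stored spectrogram of a target syllable (a
*template*).  A 256-point FFT (~8.4 ms at a 30.3 kHz sample rate) is
computed every hop (1 ms by default), and a Pearson correlation
coefficient over all time-frequency cells of the two patches decides
whether the target sound is present: the syllable is detected when the
correlation crosses the template's threshold (0.8 by default).

Column-grid convention: a magnitude column "ends" at sample index ``t``
when it is computed from the window ``[t - fft_size + 1, t]``.  The
streaming engine computes a column at every ``t`` with ``(t + 1) % hop
== 0`` and ``t + 1 >= fft_size``; :func:`offline_spectrogram` reproduces
that grid exactly so streaming and offline analyses agree bit-for-bit.
Templates use the same hop but anchor their grid so the final column
ends exactly at syllable onset + template duration (the detection time
lands inside the syllable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import get_window

from .exceptions import DegenerateInputError, DimensionError, RangeError

__all__ = [
    "SpectralParams",
    "Spectrogram",
    "Template",
    "fft_magnitude",
    "spectrogram_correlation",
    "offline_spectrogram",
    "build_template",
    "save_template",
    "load_template",
]


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of the streaming short-time FFT.

    Attributes
    ----------
    sample_rate_hz:
        Acquisition rate; 30,300 Hz by default.
    fft_size:
        Window length in samples (power of two); 256 by default,
        ~8.4 ms at the default rate.
    hop_ms:
        Nominal spacing between successive FFT columns.  The actual hop
        is ``round(hop_ms * sample_rate_hz / 1000)`` samples — at
        30.3 kHz that is 30 samples (~0.990 ms) — and every "each
        millisecond" rule in the engine counts hops, not wall time.
    taper:
        Window-function name understood by :func:`scipy.signal.get_window`
        ("hann" by default; "boxcar" for no taper).
    magnitude_scale:
        "linear" (default) or "log" (log1p of the magnitude).  Linear
        magnitudes make the template correlation exactly invariant to
        loudness.
    band_hz:
        Optional (lo, hi) frequency band restricting the correlation.
    """

    sample_rate_hz: float = 30_300.0
    fft_size: int = 256
    hop_ms: float = 1.0
    taper: str = "hann"
    magnitude_scale: str = "linear"
    band_hz: tuple[float, float] | None = None

    def __post_init__(self):
        if self.fft_size <= 0 or (self.fft_size & (self.fft_size - 1)) != 0:
            raise ValueError(f"fft_size must be a positive power of two, got {self.fft_size}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.hop <= 0:
            raise ValueError("hop must be at least one sample")
        if self.magnitude_scale not in ("linear", "log"):
            raise ValueError(f"unknown magnitude_scale {self.magnitude_scale!r}")
        if self.band_hz is not None:
            lo, hi = self.band_hz
            if not (0 <= lo < hi <= self.sample_rate_hz / 2):
                raise ValueError(f"band {self.band_hz} outside [0, Nyquist]")

    @property
    def hop(self) -> int:
        """Hop in samples."""
        return max(1, round(self.hop_ms * self.sample_rate_hz / 1000.0))

    @property
    def n_bins(self) -> int:
        return self.fft_size // 2 + 1

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.fft.rfftfreq(self.fft_size, d=1.0 / self.sample_rate_hz)

    def taper_window(self) -> np.ndarray:
        return get_window(self.taper, self.fft_size, fftbins=True)

    def ms_to_samples(self, ms: float) -> int:
        return round(ms * self.sample_rate_hz / 1000.0)

    def band_mask(self) -> np.ndarray | None:
        if self.band_hz is None:
            return None
        lo, hi = self.band_hz
        f = self.bin_freqs_hz
        return (f >= lo) & (f <= hi)


@dataclass
class Spectrogram:
    """A magnitude spectrogram patch.

    ``magnitudes`` has shape (n_bins, n_cols) with columns in
    chronological order; ``end_time`` is the sample index of the newest
    sample contributing to the last column.
    """

    magnitudes: np.ndarray
    params: SpectralParams
    end_time: int = -1

    def __post_init__(self):
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.ndim != 2:
            raise DimensionError("magnitudes must be a 2-D (n_bins, n_cols) array")
        if self.magnitudes.shape[0] != self.params.n_bins:
            raise DimensionError(
                f"{self.magnitudes.shape[0]} bins, expected {self.params.n_bins}")

    @property
    def n_cols(self) -> int:
        return self.magnitudes.shape[1]


@dataclass
class Template:
    """A spectrogram patch of a target syllable plus its detection threshold.

    The patch covers ``pre_roll_ms`` of pre-onset audio (part of the
    inter-syllable gap) followed by the first ``duration_ms`` of the
    syllable, so the end of the template — the detection time — lands
    inside the syllable.  ``threshold`` is the Pearson correlation above
    which the syllable is considered detected; it must lie strictly
    inside (-1, 1).
    """

    id: str
    patch: np.ndarray
    duration_ms: float
    pre_roll_ms: float
    threshold: float
    params: SpectralParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 2 or self.patch.shape[0] != self.params.n_bins:
            raise DimensionError(
                f"patch shape {self.patch.shape} inconsistent with "
                f"{self.params.n_bins} frequency bins")
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (-1, 1), got {self.threshold}")

    @property
    def n_cols(self) -> int:
        return self.patch.shape[1]

    @property
    def post_onset_samples(self) -> int:
        """Samples from syllable onset to the detection time (template end)."""
        return self.params.ms_to_samples(self.duration_ms)


# ---------------------------------------------------------------------------
# FFT magnitude and correlation
# ---------------------------------------------------------------------------

def fft_magnitude(window: np.ndarray, params: SpectralParams) -> np.ndarray:
    """Magnitude of the non-negative-frequency FFT of one tapered window.

    ``window`` must have exactly ``params.fft_size`` samples.  Returns a
    vector of ``params.n_bins`` magnitudes; with ``magnitude_scale ==
    "log"`` the vector is ``log(1 + magnitude)``.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (params.fft_size,):
        raise DimensionError(
            f"window has shape {window.shape}, expected ({params.fft_size},)")
    mag = np.abs(np.fft.rfft(window * params.taper_window()))
    if params.magnitude_scale == "log":
        mag = np.log1p(mag)
    return mag


def spectrogram_correlation(a: np.ndarray, b: np.ndarray,
                            band_hz: tuple[float, float] | None = None,
                            params: SpectralParams | None = None) -> float:
    """Pearson correlation between two spectrogram patches.

    All in-band time-frequency cells are flattened and correlated with
    the textbook Pearson formula.  Patches must have identical shapes.
    A zero-variance patch raises :class:`DegenerateInputError` — whether
    silence matches a template is the amplitude gate's decision, not a
    correlation convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"patch shapes differ: {a.shape} vs {b.shape}")
    if band_hz is not None:
        if params is None:
            raise ValueError("band_hz restriction requires params")
        mask = SpectralParams(
            sample_rate_hz=params.sample_rate_hz, fft_size=params.fft_size,
            hop_ms=params.hop_ms, taper=params.taper,
            magnitude_scale=params.magnitude_scale, band_hz=band_hz).band_mask()
        a = a[mask, :]
        b = b[mask, :]
    x = a.ravel()
    y = b.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(np.dot(xc, xc))
    ny = np.sqrt(np.dot(yc, yc))
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("zero-variance spectrogram patch")
    r = float(np.dot(xc, yc) / (nx * ny))
    return min(1.0, max(-1.0, r))


# ---------------------------------------------------------------------------
# Offline spectrogram (the streaming grid, computed in one pass)
# ---------------------------------------------------------------------------

def offline_spectrogram(audio: np.ndarray, params: SpectralParams,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Spectrogram of a whole recording on the streaming column grid.

    Returns ``(magnitudes, times)`` where column ``j`` ends at sample
    index ``times[j]``; columns sit at every ``t`` with ``(t + 1) % hop
    == 0`` and a full FFT window available.  This is exactly the set of
    columns the engine computes when triggered for the whole recording,
    so streaming and offline results can be compared bit-for-bit.
    """
    audio = np.asarray(audio, dtype=np.float64)
    n = audio.size
    hop, fft_size = params.hop, params.fft_size
    first = ((fft_size + hop - 1) // hop) * hop - 1  # first t with full window
    times = np.arange(first, n, hop, dtype=np.int64)
    taper = params.taper_window()
    cols = np.empty((params.n_bins, times.size), dtype=np.float64)
    for j, t in enumerate(times):
        cols[:, j] = np.abs(np.fft.rfft(audio[t - fft_size + 1:t + 1] * taper))
    if params.magnitude_scale == "log":
        cols = np.log1p(cols)
    return cols, times


def _segment_spectrogram(audio: np.ndarray, start: int, end: int,
                         params: SpectralParams) -> np.ndarray:
    """Columns over ``audio[start:end]``, grid anchored so the final column
    ends at sample ``end - 1``."""
    hop, fft_size = params.hop, params.fft_size
    seg_len = end - start
    n_cols = (seg_len - fft_size) // hop + 1
    if n_cols < 1:
        raise RangeError(
            f"segment of {seg_len} samples too short for one {fft_size}-sample window")
    taper = params.taper_window()
    cols = np.empty((params.n_bins, n_cols), dtype=np.float64)
    for j in range(n_cols):
        e = end - (n_cols - 1 - j) * hop  # exclusive window end
        cols[:, j] = np.abs(np.fft.rfft(audio[e - fft_size:e] * taper))
    if params.magnitude_scale == "log":
        cols = np.log1p(cols)
    return cols


# ---------------------------------------------------------------------------
# Template construction and serialization
# ---------------------------------------------------------------------------

def build_template(audio: np.ndarray, onset_s: float, duration_ms: float,
                   params: SpectralParams, threshold: float = 0.8,
                   pre_roll_ms: float = 10.0, id: str = "template",
                   provenance: dict | None = None) -> Template:
    """Cut a template patch out of an annotated recording.

    The patch spans ``[onset - pre_roll, onset + duration]``; its final
    column ends at ``onset + duration`` so the detection time falls
    inside the syllable (a 20 ms template over a 40 ms syllable detects
    near the syllable's middle).
    """
    audio = np.asarray(audio, dtype=np.float64)
    sr = params.sample_rate_hz
    onset = round(onset_s * sr)
    start = onset - params.ms_to_samples(pre_roll_ms)
    end = onset + params.ms_to_samples(duration_ms)
    if start < 0 or end > audio.size or onset >= audio.size:
        raise RangeError(
            f"template interval [{start}, {end}) outside recording of "
            f"{audio.size} samples")
    patch = _segment_spectrogram(audio, start, end, params)
    prov = {"onset_s": float(onset_s), "duration_ms": float(duration_ms),
            "pre_roll_ms": float(pre_roll_ms)}
    if provenance:
        prov.update(provenance)
    return Template(id=id, patch=patch, duration_ms=duration_ms,
                    pre_roll_ms=pre_roll_ms, threshold=threshold,
                    params=params, provenance=prov)


def save_template(template: Template, path: str | Path) -> None:
    """Serialize a template to a JSON sidecar file."""
    p = template.params
    doc = {
        "id": template.id,
        "duration_ms": template.duration_ms,
        "pre_roll_ms": template.pre_roll_ms,
        "threshold": template.threshold,
        "params": {
            "sample_rate_hz": p.sample_rate_hz,
            "fft_size": p.fft_size,
            "hop_ms": p.hop_ms,
            "taper": p.taper,
            "magnitude_scale": p.magnitude_scale,
            "band_hz": list(p.band_hz) if p.band_hz else None,
        },
        "provenance": template.provenance,
        "patch": template.patch.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_template(path: str | Path) -> Template:
    doc = json.loads(Path(path).read_text())
    pd = doc["params"]
    params = SpectralParams(
        sample_rate_hz=pd["sample_rate_hz"], fft_size=pd["fft_size"],
        hop_ms=pd["hop_ms"], taper=pd["taper"],
        magnitude_scale=pd["magnitude_scale"],
        band_hz=tuple(pd["band_hz"]) if pd["band_hz"] else None)
    return Template(id=doc["id"], patch=np.array(doc["patch"]),
                    duration_ms=doc["duration_ms"], pre_roll_ms=doc["pre_roll_ms"],
                    threshold=doc["threshold"], params=params,
                    provenance=doc.get("provenance", {}))
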