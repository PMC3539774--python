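"""Evaluation and behavioral statistics.

Covers four jobs: (1) matching detections against ground-truth syllable
annotations into confusion counts; (2) the half-difference
inter-syllable-interval estimator — half the detection-time difference
between a target syllable and the *second* syllable after it, which
sidesteps playback pickup contaminating the intervening syllable; (3)
the two-sample Kolmogorov-Smirnov test used to compare interval
distributions between feedback and control trials; and (4) per-day mean
+/- s.e.m. pitch summaries for long-term experiments.

Also provides :func:`offline_scan`, a one-pass sliding-window
correlation scan over a whole recording.  It shares the engine's column
grid but none of its streaming machinery (no rings, no gating, no state
machine), which makes it the natural cross-check for the streaming
engine's event log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov

from .exceptions import DegenerateInputError, InputError
from .spectral import SpectralParams, Template, offline_spectrogram, spectrogram_correlation

__all__ = [
    "ConfusionCounts",
    "KSResult",
    "DailyPitchSummary",
    "match_detections",
    "half_difference_intervals",
    "ks_two_sample",
    "daily_pitch_summary",
    "offline_scan",
]


@dataclass
class ConfusionCounts:
    """Detection/ground-truth confusion for one target syllable."""
    n_targets: int
    n_detected: int
    n_missed: int
    n_false_positive: int
    tolerance_ms: float

    @property
    def recall(self) -> float:
        return self.n_detected / self.n_targets if self.n_targets else float("nan")


@dataclass
class KSResult:
    D: float
    p: float
    n_x: int
    n_y: int


@dataclass
class DailyPitchSummary:
    day: int
    mean_hz: float
    sem_hz: float
    n: int
    single_rendition: bool = False   # s.e.m. reported as 0 by convention


def match_detections(detection_times_s: list[float], truth_onsets_s: list[float],
                     post_onset_extent_s: float = 0.0,
                     tolerance_ms: float = 10.0) -> ConfusionCounts:
    """Greedy chronological one-to-one matching of detections to targets.

    Each target's *expected* detection point is its onset plus the
    template's post-onset extent (the end-of-template detection
    convention).  Walking detections in time order, each pairs with the
    nearest unmatched expected point within the tolerance; unmatched
    targets count as missed, unmatched detections as false positives.
    """
    if tolerance_ms <= 0:
        raise InputError("tolerance must be positive")
    det = np.asarray(detection_times_s, dtype=np.float64)
    tru = np.asarray(truth_onsets_s, dtype=np.float64) + post_onset_extent_s
    if np.any(np.diff(det) < 0) or np.any(np.diff(tru) < 0):
        raise InputError("detection and truth times must be sorted")
    tol = tolerance_ms / 1000.0
    matched = np.zeros(tru.size, dtype=bool)
    n_tp = 0
    n_fp = 0
    for d in det:
        if tru.size:
            gaps = np.abs(tru - d)
            gaps[matched] = np.inf
            j = int(np.argmin(gaps)) if gaps.size else -1
        else:
            j = -1
        if j >= 0 and np.isfinite(gaps[j]) and gaps[j] <= tol:
            matched[j] = True
            n_tp += 1
        else:
            n_fp += 1
    return ConfusionCounts(n_targets=tru.size, n_detected=n_tp,
                           n_missed=int(tru.size - n_tp),
                           n_false_positive=n_fp, tolerance_ms=tolerance_ms)


def half_difference_intervals(target_times_s: np.ndarray,
                              second_following_times_s: np.ndarray) -> np.ndarray:
    """Inter-syllable intervals in ms: half the detection-time difference
    between each target syllable and the second syllable after it.

    For equally spaced consecutive syllables (spacing d) this equals d
    exactly; it avoids measuring the intervening syllable directly,
    which may be overlapped by playback pickup.
    """
    a = np.asarray(target_times_s, dtype=np.float64)
    b = np.asarray(second_following_times_s, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError("paired time arrays must have equal length")
    diff = b - a
    if np.any(diff <= 0):
        raise InputError("second-following times must exceed target times")
    return diff / 2.0 * 1000.0


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample points of the absolute
    difference between the two empirical CDFs; the p-value comes from
    the asymptotic Kolmogorov distribution at effective sample size
    ``n m / (n + m)`` — standard practice at the sample sizes of
    behavioral timing experiments (hundreds of intervals).
    """
    x = np.sort(np.asarray(x, dtype=np.float64))
    y = np.sort(np.asarray(y, dtype=np.float64))
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise InputError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(n * m / (n + m))
    p = float(kolmogorov(en * D))
    return KSResult(D=D, p=min(1.0, max(0.0, p)), n_x=n, n_y=m)


def daily_pitch_summary(renditions: list[tuple[int, float]],
                        ) -> list[DailyPitchSummary]:
    """Per-day mean pitch, s.e.m. (s.d./sqrt(n)) and rendition count.

    Days are reported in ascending order; a day with a single rendition
    gets s.e.m. 0 by convention and is flagged.
    """
    by_day: dict[int, list[float]] = {}
    for day, pitch in renditions:
        by_day.setdefault(int(day), []).append(float(pitch))
    out = []
    for day in sorted(by_day):
        vals = np.array(by_day[day])
        if vals.size == 1:
            out.append(DailyPitchSummary(day=day, mean_hz=float(vals[0]),
                                         sem_hz=0.0, n=1, single_rendition=True))
        else:
            out.append(DailyPitchSummary(
                day=day, mean_hz=float(vals.mean()),
                sem_hz=float(vals.std(ddof=1) / np.sqrt(vals.size)),
                n=int(vals.size)))
    return out


def offline_scan(audio: np.ndarray, templates: list[Template],
                 params: SpectralParams,
                 refractory_samples: dict[str, int] | None = None,
                 ) -> list[tuple[str, int, float]]:
    """Offline sliding-window correlation scan over a whole recording.

    Computes the full spectrogram in one pass on the streaming column
    grid, slides each template over every run of consecutive columns,
    and reports ``(template_id, detection_time, r)`` for every
    above-threshold correlation outside the per-template refractory.
    Zero-variance windows (true silence) never detect.
    """
    cols, times = offline_spectrogram(audio, params)
    detections: list[tuple[str, int, float]] = []
    for tmpl in sorted(templates, key=lambda t: t.id):
        k = tmpl.n_cols
        refr = (refractory_samples or {}).get(tmpl.id)
        if refr is None:
            refr = params.ms_to_samples(tmpl.pre_roll_ms + tmpl.duration_ms)
        blocked_until = 0
        for j in range(k - 1, cols.shape[1]):
            t = int(times[j])
            if t < blocked_until:
                continue
            window = cols[:, j - k + 1:j + 1]
            try:
                r = spectrogram_correlation(window, tmpl.patch,
                                            band_hz=params.band_hz, params=params)
            except DegenerateInputError:
                continue
            if r >= tmpl.threshold:
                detections.append((tmpl.id, t, r))
                blocked_until = t + refr
    detections.sort(key=lambda d: (d[1], d[0]))
    return detections
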