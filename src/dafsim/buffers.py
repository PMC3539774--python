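"""Fixed-capacity circular buffers for streaming audio and spectrogram columns.

The detection engine keeps two ring buffers: one over raw samples (so the
most recent N samples are always available in constant time) and one over
FFT magnitude columns (so a spectrogram of the recent past can be
assembled without recomputing any FFT).  Both overwrite their oldest
element when full and never reorder their contents; reads never mutate
state.

Time is carried as an integer sample index, with sample 0 the first
sample of the stream.  ``SampleRing.total_pushed - 1`` is therefore the
index of the newest sample.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DimensionError, RangeError

__all__ = ["SampleRing", "SpectroRing"]


class SampleRing:
    """Circular buffer over raw audio samples.

    Parameters
    ----------
    capacity:
        Maximum number of samples retained.  The engine default is at
        least two seconds of audio, comfortably above the longest
        template (100 ms), so template windows never hit capacity.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        self.capacity = int(capacity)
        self._buf = np.zeros(self.capacity, dtype=np.float64)
        self._write = 0  # next slot to write
        self.total_pushed = 0

    def __len__(self) -> int:
        return min(self.total_pushed, self.capacity)

    def push(self, sample: float) -> None:
        """Append one sample, discarding the oldest if full."""
        self._buf[self._write] = sample
        self._write = (self._write + 1) % self.capacity
        self.total_pushed += 1

    def extend(self, samples: np.ndarray) -> None:
        """Append many samples; bit-identical to repeated :meth:`push`."""
        samples = np.asarray(samples, dtype=np.float64)
        n = samples.size
        if n == 0:
            return
        if n >= self.capacity:
            # only the tail survives
            self._buf[:] = samples[n - self.capacity:]
            self._write = 0
        else:
            end = self._write + n
            if end <= self.capacity:
                self._buf[self._write:end] = samples
            else:
                k = self.capacity - self._write
                self._buf[self._write:] = samples[:k]
                self._buf[:end - self.capacity] = samples[k:]
            self._write = end % self.capacity
        self.total_pushed += n

    def latest_window(self, n: int) -> np.ndarray:
        """Return the last ``n`` pushed samples, oldest first.

        Raises :class:`RangeError` unless ``1 <= n <= min(capacity,
        total_pushed)``.
        """
        if n < 1 or n > min(self.capacity, self.total_pushed):
            raise RangeError(
                f"window of {n} samples not available "
                f"(capacity={self.capacity}, pushed={self.total_pushed})")
        start = self._write - n
        if start >= 0:
            return self._buf[start:self._write].copy()
        return np.concatenate([self._buf[start:], self._buf[:self._write]])


class SpectroRing:
    """Circular buffer over FFT magnitude columns.

    Each column is a vector of ``n_bins`` magnitudes; ``column_times``
    records the sample index of the newest sample that contributed to
    each stored column.  All columns must share the same bin count.
    """

    def __init__(self, capacity: int, n_bins: int):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        if n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {n_bins}")
        self.capacity = int(capacity)
        self.n_bins = int(n_bins)
        self._buf = np.zeros((self.n_bins, self.capacity), dtype=np.float64)
        self._times = np.zeros(self.capacity, dtype=np.int64)
        self._write = 0
        self.total_pushed = 0

    def __len__(self) -> int:
        return min(self.total_pushed, self.capacity)

    def clear(self) -> None:
        """Forget all stored columns (counters keep advancing afterwards)."""
        self._write = 0
        self.total_pushed = 0

    def push(self, column: np.ndarray, time: int) -> None:
        """Append one magnitude column with its end-sample index."""
        column = np.asarray(column, dtype=np.float64)
        if column.shape != (self.n_bins,):
            raise DimensionError(
                f"column has shape {column.shape}, expected ({self.n_bins},)")
        self._buf[:, self._write] = column
        self._times[self._write] = time
        self._write = (self._write + 1) % self.capacity
        self.total_pushed += 1

    def latest_spectrogram(self, k: int) -> np.ndarray:
        """Return the last ``k`` columns in chronological order, shape (n_bins, k)."""
        if k < 1 or k > len(self):
            raise RangeError(
                f"{k} columns not available (stored={len(self)})")
        start = self._write - k
        if start >= 0:
            return self._buf[:, start:self._write].copy()
        return np.concatenate(
            [self._buf[:, start:], self._buf[:, :self._write]], axis=1)

    def latest_times(self, k: int) -> np.ndarray:
        """Sample indices (newest contributing sample) of the last ``k`` columns."""
        if k < 1 or k > len(self):
            raise RangeError(
                f"{k} columns not available (stored={len(self)})")
        start = self._write - k
        if start >= 0:
            return self._times[start:self._write].copy()
        return np.concatenate([self._times[start:], self._times[:self._write]])
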