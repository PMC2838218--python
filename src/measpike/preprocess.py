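"""Band-pass filtering and the windowing/percentile primitives shared by all
noise estimators.

Two conventions are fixed here and used everywhere downstream:

* the data stream is split into contiguous, non-overlapping 10 ms windows
  (a trailing partial window is discarded);
* percentiles of a sorted n-vector are taken by the hardware-friendly index
  rule ``I_k = 0.5 + n*k/100`` truncated to an integer and clamped to
  ``[1, n]`` (1-based).  For n = 100, k = 25 this selects the 25th sorted
  element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording

WINDOW_S = 0.010  # noise-estimation window length, seconds


def window_length(fs_hz: float, window_s: float = WINDOW_S) -> int:
    """Number of samples in one estimation window (round(10 ms x fs))."""
    n = round(window_s * fs_hz)
    if n < 1:
        raise ValueError("window shorter than one sample")
    return n


@dataclass
class WindowView:
    """Contiguous non-overlapping windows over a trace.

    The trailing partial window, if any, is dropped.
    """

    samples: np.ndarray
    window_len: int

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.samples.size // self.window_len

    def as_matrix(self) -> np.ndarray:
        """All complete windows stacked as an (n_windows, window_len) array."""
        n = self.n_windows * self.window_len
        return self.samples[:n].reshape(self.n_windows, self.window_len)

    def __iter__(self):
        m = self.as_matrix()
        for i in range(self.n_windows):
            yield m[i]


def bandpass_filter(
    rec: Recording,
    low_hz: float = 150.0,
    high_hz: float = 2500.0,
    order: int = 2,
    zero_phase: bool = False,
) -> Recording:
    """Butterworth band-pass filter a trace.

    Causal single-pass filtering by default, matching a streaming
    implementation; ``zero_phase=True`` applies the filter forward and
    backward instead (``sosfiltfilt``).
    """
    nyq = rec.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={rec.fs_hz} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.samples)
    else:
        filtered = signal.sosfilt(sos, rec.samples)
    return rec.with_samples(filtered)


def window_rms(window: np.ndarray) -> float:
    """Root-mean-square amplitude of one window (microvolts)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(window**2)))


def percentile_index(n: int, k: float) -> int:
    """1-based sorted index selected for the k-th percentile of n values.

    ``I_k = 0.5 + n*k/100``, truncated to an integer (as a shift-and-compare
    hardware datapath would) and clamped to ``[1, n]``.
    """
    if n < 1:
        raise ValueError("empty vector")
    if not 0 < k < 100:
        raise ValueError(f"percentile k must be in (0, 100), got {k}")
    i = math.floor(0.5 + n * k / 100.0)
    return min(max(i, 1), n)


def percentile(values: np.ndarray, k: float, assume_sorted: bool = False) -> float:
    """k-th percentile of a vector under the package's index convention.

    Sorts ascending unless ``assume_sorted``; returns the element at
    :func:`percentile_index`.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    if not assume_sorted:
        values = np.sort(values)
    return float(values[percentile_index(values.size, k) - 1])
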