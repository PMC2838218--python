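"""Five streaming noise-level estimators and their detection thresholds.

Each estimator consumes contiguous 10 ms windows of the band-pass filtered
trace and maintains positive/negative detection thresholds as a multiple of
its running noise-level estimate:

* ``BandFlt`` — one-shot: 25th percentile of the first 300 window RMS
  values, times 4; fixed thereafter.
* ``Limada`` — per-window 2nd/30th voltage percentiles gate "clean"
  windows; the estimate is an exponential smoother
  ``est(k) = 0.99*est(k-1) + 0.01*|V.02|`` over clean windows, times 4.
* ``AdaFlt`` — 40th percentiles of window maxima/minima (M.4, m.4) over
  batches of 128 retained windows, retaining one window in ten;
  ``est_p(k) = 0.9*est_p(k-1) + 0.1*M.4`` (and mirrored for minima),
  times 2, with independent positive and negative thresholds.
* ``AdaFlt128`` — AdaFlt retaining every window, so it refreshes every 128
  raw windows instead of every 1280 (faster, more noise-sensitive).
* ``AdaBandFlt`` — adaptive BandFlt: 25th percentile of each batch of 100
  window RMS values (N.25), smoothed as
  ``est(k) = 0.8*est(k-1) + 0.2*N.25``, times 4.

All estimators share the same contract: ``process_window`` returns the
current :class:`ThresholdPair` (``valid`` is False until initialization
completes), and ``run`` maps a whole recording to a
:class:`ThresholdTrace`.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowView, percentile, window_length, window_rms
from .recording import Recording


@dataclass(frozen=True)
class ThresholdPair:
    """Positive/negative detection thresholds in microvolts."""

    pos: float
    neg: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (self.pos >= 0 >= self.neg):
            raise ValueError(f"need pos >= 0 >= neg, got ({self.pos}, {self.neg})")


INVALID = ThresholdPair(0.0, 0.0, valid=False)


def thresholds_from_estimate(
    estimate: float | tuple[float, float], multiplier: float
) -> ThresholdPair:
    """Thresholds as a multiple of the noise-level estimate.

    A scalar estimate gives symmetric thresholds; a ``(pos, neg)`` pair
    (the negative estimate itself negative) gives asymmetric ones.
    """
    if multiplier <= 0:
        raise ValueError("threshold multiplier must be positive")
    if isinstance(estimate, tuple):
        est_p, est_n = estimate
        if est_p < 0:
            raise ValueError("positive noise estimate must be non-negative")
        if est_n > 0:
            raise ValueError("negative noise estimate must be non-positive")
        return ThresholdPair(multiplier * est_p, multiplier * est_n)
    if estimate < 0:
        raise ValueError("noise estimate must be non-negative")
    return ThresholdPair(multiplier * estimate, -multiplier * estimate)


@dataclass
class ThresholdTrace:
    """Per-window threshold history emitted by an estimator run."""

    pos: np.ndarray
    neg: np.ndarray
    valid: np.ndarray
    window_len: int
    fs_hz: float

    @property
    def n_windows(self) -> int:
        return self.pos.size

    def first_valid_window(self) -> int | None:
        idx = np.flatnonzero(self.valid)
        return int(idx[0]) if idx.size else None

    def per_sample(self, n_samples: int, pre_init: str = "backfill") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand to per-sample (pos, neg, scan_mask) arrays.

        Zero-order hold within each window; ``pre_init`` controls samples
        before the first valid threshold: ``"backfill"`` (default, for
        offline analysis) applies the first valid pair retroactively,
        ``"skip"`` masks them out of the scan.
        """
        if pre_init not in ("backfill", "skip"):
            raise ValueError("pre_init must be 'backfill' or 'skip'")
        pos = np.repeat(self.pos, self.window_len)
        neg = np.repeat(self.neg, self.window_len)
        ok = np.repeat(self.valid, self.window_len)
        if pos.size < n_samples:  # trailing partial window: hold last value
            pad = n_samples - pos.size
            pos = np.concatenate([pos, np.full(pad, self.pos[-1] if self.pos.size else 0.0)])
            neg = np.concatenate([neg, np.full(pad, self.neg[-1] if self.neg.size else 0.0)])
            ok = np.concatenate([ok, np.full(pad, bool(self.valid[-1]) if self.valid.size else False)])
        pos, neg, ok = pos[:n_samples], neg[:n_samples], ok[:n_samples]
        fv = self.first_valid_window()
        if fv is not None and pre_init == "backfill":
            s = fv * self.window_len
            pos[:s] = self.pos[fv]
            neg[:s] = self.neg[fv]
            ok[:s] = True
        return pos, neg, ok


class NoiseEstimator(ABC):
    """Common streaming contract for the five estimators."""

    name: str = "base"

    def __init__(self, multiplier: float):
        if multiplier <= 0:
            raise ValueError("threshold multiplier must be positive")
        self.multiplier = multiplier
        self.k = 0  # windows consumed

    @abstractmethod
    def process_window(self, window: np.ndarray) -> ThresholdPair:
        """Consume one 10 ms window, return the current thresholds."""

    def run(self, rec: Recording) -> ThresholdTrace:
        """Process a whole recording window-by-window."""
        wl = window_length(rec.fs_hz)
        view = WindowView(rec.samples, wl)
        pos, neg, ok = [], [], []
        for w in view:
            t = self.process_window(w)
            pos.append(t.pos)
            neg.append(t.neg)
            ok.append(t.valid)
        return ThresholdTrace(
            pos=np.array(pos), neg=np.array(neg), valid=np.array(ok, dtype=bool),
            window_len=wl, fs_hz=rec.fs_hz,
        )


class BandFlt(NoiseEstimator):
    """Fixed threshold from the 25th percentile of 300 window RMS values."""

    name = "bandflt"

    def __init__(self, multiplier: float = 4.0, n_init: int = 300):
        super().__init__(multiplier)
        self.n_init = n_init
        self.rms_buffer: list[float] = []
        self.noise_est: float | None = None
        self._threshold = INVALID

    def process_window(self, window: np.ndarray) -> ThresholdPair:
        self.k += 1
        if self.noise_est is None:
            self.rms_buffer.append(window_rms(window))
            if len(self.rms_buffer) == self.n_init:
                self.noise_est = percentile(np.array(self.rms_buffer), 25)
                self._threshold = thresholds_from_estimate(self.noise_est, self.multiplier)
        return self._threshold


def limada_is_clean(
    window: np.ndarray, ratio_limit: float = 5.0, nonzero_eps: float = 1e-3
) -> tuple[bool, float, float]:
    """Clean-window test on the 2nd and 30th voltage percentiles.

    A window is clean iff ``V.02/V.30 < ratio_limit`` (no spike drives the
    extreme low percentile far beyond the bulk) and ``|V.30|`` is
    significantly non-zero (the data are not blanked).  Percentiles are of
    the signed voltages; for zero-mean noise both are negative and the
    ratio is positive.  Returns (clean, V02, V30).
    """
    window = np.asarray(window, dtype=float)
    v = np.sort(window)
    v02 = percentile(v, 2, assume_sorted=True)
    v30 = percentile(v, 30, assume_sorted=True)
    if abs(v30) <= nonzero_eps:
        return False, v02, v30
    return bool(v02 / v30 < ratio_limit), v02, v30


class Limada(NoiseEstimator):
    """Clean-window gated exponential smoother of |V.02|."""

    name = "limada"

    def __init__(
        self,
        multiplier: float = 4.0,
        n_init_clean: int = 100,
        ratio_limit: float = 5.0,
        nonzero_eps: float = 1e-3,
    ):
        super().__init__(multiplier)
        self.n_init_clean = n_init_clean
        self.ratio_limit = ratio_limit
        self.nonzero_eps = nonzero_eps
        self.init_values: list[float] = []
        self.noise_est: float | None = None
        self._threshold = INVALID

    def process_window(self, window: np.ndarray) -> ThresholdPair:
        self.k += 1
        clean, v02, _ = limada_is_clean(window, self.ratio_limit, self.nonzero_eps)
        if not clean:
            return self._threshold
        if self.noise_est is None:
            self.init_values.append(abs(v02))
            if len(self.init_values) == self.n_init_clean:
                # init: mean of the collected |V.02| values (smooth start)
                self.noise_est = float(np.mean(self.init_values))
        else:
            self.noise_est = 0.99 * self.noise_est + 0.01 * abs(v02)
        if self.noise_est is not None:
            self._threshold = thresholds_from_estimate(self.noise_est, self.multiplier)
        return self._threshold


class AdaFlt(NoiseEstimator):
    """Window-extrema percentile estimator with decimated refresh.

    Initializes from the extrema of the first 128 raw windows; afterwards
    retains one window in ``decimation`` and refreshes via the 0.9/0.1
    smoother whenever 128 retained windows have accumulated.
    """

    name = "adaflt"

    def __init__(
        self,
        multiplier: float = 2.0,
        n_init: int = 128,
        decimation: int = 10,
        refresh_count: int = 128,
    ):
        super().__init__(multiplier)
        self.n_init = n_init
        self.decimation = decimation
        self.refresh_count = refresh_count
        self.max_buffer: list[float] = []
        self.min_buffer: list[float] = []
        self.noise_est_p: float | None = None
        self.noise_est_n: float | None = None
        self._since_init = 0  # raw windows seen after initialization
        self._threshold = INVALID

    def _esteems(self) -> tuple[float, float]:
        m4 = percentile(np.array(self.max_buffer), 40)
        n4 = percentile(np.array(self.min_buffer), 40)
        return m4, n4

    def _set_threshold(self) -> None:
        # estimates may have either sign on pathological input; clamp so the
        # threshold contract (pos >= 0 >= neg) holds
        p = max(self.noise_est_p, 0.0)
        n = min(self.noise_est_n, 0.0)
        self._threshold = thresholds_from_estimate((p, n), self.multiplier)

    def process_window(self, window: np.ndarray) -> ThresholdPair:
        self.k += 1
        window = np.asarray(window, dtype=float)
        if self.noise_est_p is None:
            self.max_buffer.append(float(window.max()))
            self.min_buffer.append(float(window.min()))
            if len(self.max_buffer) == self.n_init:
                m4, n4 = self._esteems()
                self.noise_est_p, self.noise_est_n = m4, n4
                self.max_buffer, self.min_buffer = [], []
                self._set_threshold()
            return self._threshold
        self._since_init += 1
        if self._since_init % self.decimation == 0:  # retain one in `decimation`
            self.max_buffer.append(float(window.max()))
            self.min_buffer.append(float(window.min()))
            if len(self.max_buffer) == self.refresh_count:
                m4, n4 = self._esteems()
                self.noise_est_p = 0.9 * self.noise_est_p + 0.1 * m4
                self.noise_est_n = 0.9 * self.noise_est_n + 0.1 * n4
                self.max_buffer, self.min_buffer = [], []
                self._set_threshold()
        return self._threshold


class AdaFlt128(AdaFlt):
    """AdaFlt refreshing every 128 raw windows (no decimation)."""

    name = "adaflt128"

    def __init__(self, multiplier: float = 2.0, n_init: int = 128, refresh_count: int = 128):
        super().__init__(multiplier, n_init, decimation=1, refresh_count=refresh_count)


class AdaBandFlt(NoiseEstimator):
    """Adaptive BandFlt: smoothed batch 25th percentiles of window RMS."""

    name = "adabandflt"

    def __init__(self, multiplier: float = 4.0, batch: int = 100):
        super().__init__(multiplier)
        self.batch = batch
        self.rms_buffer: list[float] = []
        self.noise_est: float | None = None
        self._threshold = INVALID

    def process_window(self, window: np.ndarray) -> ThresholdPair:
        self.k += 1
        self.rms_buffer.append(window_rms(window))
        if len(self.rms_buffer) == self.batch:
            n25 = percentile(np.array(self.rms_buffer), 25)
            if self.noise_est is None:
                self.noise_est = n25
            else:
                self.noise_est = 0.8 * self.noise_est + 0.2 * n25
            self.rms_buffer = []
            self._threshold = thresholds_from_estimate(self.noise_est, self.multiplier)
        return self._threshold


ESTIMATORS: dict[str, type[NoiseEstimator]] = {
    cls.name: cls for cls in (BandFlt, Limada, AdaFlt, AdaFlt128, AdaBandFlt)
}


def make_estimator(name: str, multiplier: float | None = None) -> NoiseEstimator:
    """Instantiate an estimator by name, optionally overriding the multiplier."""
    try:
        cls = ESTIMATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown estimator {name!r}; choose from {sorted(ESTIMATORS)}"
        ) from None
    return cls(multiplier) if multiplier is not None else cls()


def thresholds_to_frame(trace: ThresholdTrace):
    """Threshold history as a tidy table (for CSV export / audit plots)."""
    import pandas as pd

    t = np.arange(trace.n_windows) * trace.window_len / trace.fs_hz
    return pd.DataFrame(
        {
            "window_index": np.arange(trace.n_windows),
            "t_s": t,
            "pos_uv": trace.pos,
            "neg_uv": trace.neg,
            "valid": trace.valid,
        }
    )
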