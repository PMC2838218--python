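"""Screening-test evaluation of a detector against ground truth, and the
initialization-complexity comparison between the two best estimators.

Detections are matched one-to-one to ground-truth events within a time
tolerance; matched detections are true positives, unmatched detections
false positives, unmatched truths false negatives.  True negatives are
defined over the enumerable population of candidate noise peaks (local
extrema of the filtered trace away from any true event), so they exist
only for simulated or annotated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import SpikeEvent
from .recording import Recording


@dataclass
class MatchConfig:
    tolerance_ms: float = 1.0
    polarity_strict: bool = False

    def __post_init__(self) -> None:
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance must be positive")


def _event_times(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        return events["time_s"].to_numpy(dtype=float)
    return np.array([e.time_s for e in events], dtype=float)


def _event_polarities(events) -> np.ndarray | None:
    if isinstance(events, pd.DataFrame):
        if "polarity" in events.columns:
            return events["polarity"].to_numpy()
        return None
    return np.array([e.polarity for e in events])


def match_events(
    detected,
    truth,
    cfg: MatchConfig | None = None,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy nearest-first one-to-one pairing of detections and truths.

    Both inputs may be event lists or data frames with a ``time_s`` column.
    All (detection, truth) pairs within tolerance are ranked by |dt| and
    assigned greedily, each side used at most once.  Returns
    (TP, FP, FN, pairing) where pairing holds (detected_i, truth_j) index
    pairs.
    """
    cfg = cfg or MatchConfig()
    tol = cfg.tolerance_ms * 1e-3
    td = _event_times(detected)
    tt = _event_times(truth)
    pd_, pt = (_event_polarities(detected), _event_polarities(truth))
    check_pol = cfg.polarity_strict and pd_ is not None and pt is not None
    order_t = np.argsort(tt, kind="stable")
    tt_sorted = tt[order_t]
    pairs: list[tuple[float, int, int]] = []
    for i, t in enumerate(td):
        lo = np.searchsorted(tt_sorted, t - tol, side="left")
        hi = np.searchsorted(tt_sorted, t + tol, side="right")
        for js in range(lo, hi):
            j = int(order_t[js])
            if check_pol and pd_[i] != pt[j]:
                continue
            pairs.append((abs(t - tt[j]), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairing: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairing.append((i, j))
    tp = len(pairing)
    fp = td.size - tp
    fn = tt.size - tp
    return tp, fp, fn, pairing


def candidate_noise_peaks(
    filtered: Recording,
    truth,
    cfg: MatchConfig | None = None,
    min_abs_uv: float = 0.0,
) -> np.ndarray:
    """Sample indices of candidate noise peaks.

    Strict local extrema of the filtered trace lying outside +/-tolerance
    of every ground-truth event (optionally above a minimum |amplitude|).
    """
    cfg = cfg or MatchConfig()
    x = filtered.samples
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
    peaks = np.sort(np.concatenate([maxima, minima]))
    if min_abs_uv > 0:
        peaks = peaks[np.abs(x[peaks]) >= min_abs_uv]
    tol = int(round(cfg.tolerance_ms * 1e-3 * filtered.fs_hz))
    tt = _event_times(truth)
    truth_idx = np.round((tt - filtered.t0_s) * filtered.fs_hz).astype(int)
    truth_idx.sort()
    pos = np.searchsorted(truth_idx, peaks)
    near_next = np.zeros(peaks.size, dtype=bool)
    has_next = pos < truth_idx.size
    near_next[has_next] = truth_idx[pos[has_next]] - peaks[has_next] <= tol
    near_prev = np.zeros(peaks.size, dtype=bool)
    has_prev = pos > 0
    near_prev[has_prev] = peaks[has_prev] - truth_idx[pos[has_prev] - 1] <= tol
    return peaks[~(near_next | near_prev)]


def count_true_negatives(
    filtered: Recording,
    truth,
    detections,
    cfg: MatchConfig | None = None,
    min_abs_uv: float = 0.0,
) -> int:
    """Noise peaks the detector correctly left alone.

    TN = candidate noise peaks with no detection within tolerance.  Needs
    ground truth (simulation or annotation); undefined for blind data.
    """
    if truth is None:
        raise ValueError("true negatives are undefined without ground truth")
    cfg = cfg or MatchConfig()
    peaks = candidate_noise_peaks(filtered, truth, cfg, min_abs_uv)
    if peaks.size == 0:
        return 0
    tol = int(round(cfg.tolerance_ms * 1e-3 * filtered.fs_hz))
    det_t = _event_times(detections)
    det_idx = np.sort(np.round((det_t - filtered.t0_s) * filtered.fs_hz).astype(int))
    if det_idx.size == 0:
        return int(peaks.size)
    pos = np.searchsorted(det_idx, peaks)
    near = np.zeros(peaks.size, dtype=bool)
    has_next = pos < det_idx.size
    near[has_next] |= det_idx[pos[has_next]] - peaks[has_next] <= tol
    has_prev = pos > 0
    near[has_prev] |= peaks[has_prev] - det_idx[pos[has_prev] - 1] <= tol
    return int(np.sum(~near))


@dataclass
class ScreeningResult:
    """Confusion counts and the four screening ratios.

    A ratio whose denominator is zero is None, with the reason recorded in
    ``undefined``.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    Se: float | None
    Sp: float | None
    PPV: float | None
    NPV: float | None
    undefined: dict[str, str]

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "Se": self.Se, "Sp": self.Sp, "PPV": self.PPV, "NPV": self.NPV,
            "undefined": self.undefined,
        }


def screening_stats(TP: int, FP: int, TN: int, FN: int) -> ScreeningResult:
    """Sensitivity, specificity, PPV and NPV from confusion counts."""
    for name, v in (("TP", TP), ("FP", FP), ("TN", TN), ("FN", FN)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if TP == FP == TN == FN == 0:
        raise ValueError("all four counts are zero; screening test undefined")
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined[name] = "zero denominator"
            return None
        return num / den

    return ScreeningResult(
        TP=TP, FP=FP, TN=TN, FN=FN,
        Se=ratio(TP, TP + FN, "Se"),
        Sp=ratio(TN, TN + FP, "Sp"),
        PPV=ratio(TP, TP + FP, "PPV"),
        NPV=ratio(TN, TN + FN, "NPV"),
        undefined=undefined,
    )


def screen_detector(
    filtered: Recording,
    detections,
    truth,
    cfg: MatchConfig | None = None,
    min_abs_uv: float = 0.0,
) -> ScreeningResult:
    """Full screening test of a detector run against ground truth."""
    cfg = cfg or MatchConfig()
    tp, fp, fn, _ = match_events(detections, truth, cfg)
    tn = count_true_negatives(filtered, truth, detections, cfg, min_abs_uv)
    return screening_stats(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Initialization-complexity comparison (worst case, window length N samples,
# F channels).


def limada_init_cost(F: float, N: float) -> float:
    """Worst-case threshold-initialization cost of the clean-window
    estimator: 100 clean windows, each needing percentiles of N samples
    (quadratic worst-case sort), across F channels."""
    return 100.0 * F * N**2


def adabandflt_init_cost(F: float) -> float:
    """Worst-case threshold-initialization cost of the adaptive RMS
    estimator: sorting 100 collected RMS values (quadratic worst case)
    across F channels; independent of the window length."""
    return 100.0**2 * F


def initialization_complexity_crossover(f_values=(1.0, 2.0, 5.0, 7.0, 100.0)) -> float:
    """Window length N* at which the two initialization costs are equal.

    Solves 100*F*N^2 = 100^2*F; the channel count F cancels, which is
    verified numerically over ``f_values``.  For N above the returned value
    the clean-window estimator is strictly more expensive.
    """
    n_star = math.sqrt(adabandflt_init_cost(1.0) / limada_init_cost(1.0, 1.0))
    for f in f_values:
        if f <= 0:
            raise ValueError("F must be positive")
        assert math.isclose(
            limada_init_cost(f, n_star), adabandflt_init_cost(f), rel_tol=1e-12
        ), "crossover should not depend on F"
    return n_star
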