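"""Bipolar threshold-crossing detection, peak validation, and 2 ms waveform
extraction with tallest-peak alignment.

Detection emits one candidate per contiguous supra-threshold excursion
(positive excursions above the positive threshold, negative below the
negative one), located at the excursion's extremum.  Validation then
suppresses double detections of unitary events: within a +/-1 ms window a
candidate survives only if it is the highest-|amplitude| candidate of
either polarity there, and if half its amplitude exceeds every other
same-polarity candidate in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimators import ThresholdTrace
from .recording import Recording


@dataclass(frozen=True)
class SpikeEvent:
    """A detected spike: tallest-peak sample index, polarity, amplitude."""

    peak_index: int
    time_s: float
    polarity: str  # "+" or "-"
    peak_amplitude_uv: float
    validated: bool = False


def _excursion_peaks(samples: np.ndarray, mask: np.ndarray, sign: int) -> list[int]:
    """Extremum index of every contiguous True run in ``mask``.

    Ties within a run go to the earliest sample.
    """
    peaks = []
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate([[0], starts])
    if mask.size and mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    for a, b in zip(starts, stops):
        seg = samples[a:b]
        i = int(np.argmax(seg)) if sign > 0 else int(np.argmin(seg))
        peaks.append(a + i)
    return peaks


def detect_threshold_crossings(
    filtered: Recording,
    thresholds: ThresholdTrace,
    pre_init: str = "backfill",
) -> list[SpikeEvent]:
    """One candidate per supra-threshold excursion of the filtered trace.

    The threshold at sample t is the most recent valid pair (zero-order
    hold); ``pre_init`` selects how samples before the first valid pair are
    handled ("backfill" applies it retroactively, "skip" excludes them).
    """
    x = filtered.samples
    pos, neg, ok = thresholds.per_sample(x.size, pre_init=pre_init)
    events: list[SpikeEvent] = []
    for sign, mask in (
        (+1, ok & (x > pos)),
        (-1, ok & (x < neg)),
    ):
        for p in _excursion_peaks(x, mask, sign):
            events.append(
                SpikeEvent(
                    peak_index=p,
                    time_s=filtered.t0_s + p / filtered.fs_hz,
                    polarity="+" if sign > 0 else "-",
                    peak_amplitude_uv=float(x[p]),
                    validated=False,
                )
            )
    events.sort(key=lambda e: e.peak_index)
    return events


def validate_events(
    candidates: list[SpikeEvent],
    filtered: Recording,
    window_ms: float = 1.0,
    keep_larger: bool = False,
) -> tuple[list[SpikeEvent], int]:
    """Apply the +/-1 ms double-detection suppression rule.

    A candidate at sample p is validated iff, within the window
    ``[p - 1 ms, p + 1 ms]``:

    (a) its absolute amplitude is the largest absolute value the filtered
        trace attains there, of either polarity (an exact tie goes to the
        earlier sample), and
    (b) 50% of its amplitude exceeds the amplitude of every *other
        detected candidate* of the same polarity in the window.

    Rule (a) is evaluated against the trace itself, so secondary features
    of a large spike (an opposite-polarity lobe, a filter-ripple dip) can
    never be validated as events of their own even when the spike's
    detected peak lies outside their window.  Rule (b) compares against
    competing detections only — its job is suppressing double detections,
    and comparing against every noise wiggle would instead veto genuine
    spikes via their own flanks.

    With ``keep_larger`` the literal rule (b) is waived for the candidate
    that already won rule (a), so of two comparable same-polarity peaks the
    larger is kept instead of both being rejected.

    Candidates whose window extends past the trace boundary are discarded
    (second return value counts them).  Validation depends only on the
    trace and the candidate set, so it is order-independent and
    idempotent.
    """
    half = int(round(window_ms * 1e-3 * filtered.fs_hz))
    x = filtered.samples
    n = filtered.n_samples
    idx = np.array([c.peak_index for c in candidates])
    order = np.argsort(idx, kind="stable")
    validated: list[SpikeEvent] = []
    dropped_boundary = 0
    for oi in order:
        c = candidates[oi]
        p = c.peak_index
        if p - half < 0 or p + half >= n:
            dropped_boundary += 1
            continue
        window = np.abs(x[p - half : p + half + 1])
        ac = abs(c.peak_amplitude_uv)
        m = window.max()
        # rule (a): highest |peak| of either polarity in the window
        if m > ac or (m == ac and (p - half) + int(np.argmax(window)) < p):
            continue
        if not keep_larger:
            # rule (b): half the amplitude beats same-polarity candidates
            near = np.flatnonzero((np.abs(idx - p) <= half) & (idx != p))
            if any(
                candidates[j].polarity == c.polarity
                and 0.5 * ac <= abs(candidates[j].peak_amplitude_uv)
                for j in near
            ):
                continue
        validated.append(replace(c, validated=True))
    validated.sort(key=lambda e: e.peak_index)
    return validated, dropped_boundary


@dataclass
class WaveformMatrix:
    """Peak-aligned spike snippets: N waveforms x c samples (microvolts)."""

    waveforms: np.ndarray  # (N, c)
    events: list[SpikeEvent]  # the events each row was cut around
    alignment_offset: int  # column of the tallest peak
    fs_hz: float
    n_dropped_boundary: int = 0

    @property
    def n_waveforms(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]


def extract_waveforms(
    filtered: Recording,
    events: list[SpikeEvent],
    window_ms: float = 2.0,
) -> WaveformMatrix:
    """Cut a symmetric window around each event's tallest peak.

    At 25 kHz the 2 ms window is c = 50 samples, with the peak aligned at
    column floor(c/2) = 25.  Events too close to the trace boundary are
    dropped and counted.
    """
    c = int(round(window_ms * 1e-3 * filtered.fs_hz))
    offset = c // 2
    rows, kept = [], []
    dropped = 0
    for e in events:
        start = e.peak_index - offset
        if start < 0 or start + c > filtered.n_samples:
            dropped += 1
            continue
        rows.append(filtered.samples[start : start + c])
        kept.append(e)
    wf = np.array(rows) if rows else np.empty((0, c))
    return WaveformMatrix(
        waveforms=wf,
        events=kept,
        alignment_offset=offset,
        fs_hz=filtered.fs_hz,
        n_dropped_boundary=dropped,
    )


def events_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_index": e.peak_index,
                "time_s": e.time_s,
                "polarity": e.polarity,
                "peak_amplitude_uv": e.peak_amplitude_uv,
                "validated": e.validated,
            }
            for e in events
        ],
        columns=["peak_index", "time_s", "polarity", "peak_amplitude_uv", "validated"],
    )


def frame_to_events(df: pd.DataFrame) -> list[SpikeEvent]:
    return [
        SpikeEvent(
            peak_index=int(r.peak_index),
            time_s=float(r.time_s),
            polarity=str(r.polarity),
            peak_amplitude_uv=float(r.peak_amplitude_uv),
            validated=bool(r.validated),
        )
        for r in df.itertuples()
    ]
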