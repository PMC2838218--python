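"""Ground-truthed synthetic MEA recordings.

A simulated recording is a zero baseline carrying triangular action-potential
templates (simple positive/negative triangles plus two overlapped,
temporally shifted complexes), mixed with band-limited (150-2500 Hz, 2nd
order Butterworth) white Gaussian noise scaled to an exact target SNR.
Defaults: 60 s at 25 kHz, 600 events, SNR 5 dB, five waveform classes.
Everything is reproducible from a single integer seed, and every event is
logged in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording


@dataclass
class WaveTemplate:
    """A spike waveform template (amplitudes in microvolts)."""

    samples: np.ndarray
    class_id: str
    polarity: str  # "+", "-" or "biphasic"
    peak_amplitude_uv: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def apex_offset(self) -> int:
        """Offset of the tallest |peak| within the template (first on ties)."""
        return int(np.argmax(np.abs(self.samples)))


def make_triangle_template(
    peak_amplitude_uv: float,
    polarity: str,
    n_samples: int = 20,
    class_id: str | None = None,
) -> WaveTemplate:
    """Symmetric triangular spike: linear ramps with the apex at the center
    sample, signed by polarity, zero baseline off-template."""
    if peak_amplitude_uv <= 0:
        raise ValueError(f"peak amplitude must be positive, got {peak_amplitude_uv}")
    if n_samples < 3:
        raise ValueError(f"template needs >= 3 samples, got {n_samples}")
    if polarity not in ("+", "-"):
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    apex = n_samples // 2
    half_width = apex  # samples from apex to the (left) baseline
    i = np.arange(n_samples)
    shape = np.clip(1.0 - np.abs(i - apex) / half_width, 0.0, None)
    sign = 1.0 if polarity == "+" else -1.0
    return WaveTemplate(
        samples=sign * peak_amplitude_uv * shape,
        class_id=class_id or f"tri{polarity}{peak_amplitude_uv:g}",
        polarity=polarity,
        peak_amplitude_uv=peak_amplitude_uv,
    )


def make_complex_template(
    base: WaveTemplate,
    shift_samples: int,
    second_polarity: str,
    second_scale: float = 1.0,
    class_id: str | None = None,
) -> WaveTemplate:
    """Two overlapped, temporally shifted triangular waves.

    The template is the sample-wise sum of ``base`` and a shifted copy whose
    sign follows ``second_polarity`` and whose amplitude is scaled by
    ``second_scale``.  Length is ``len(base) + shift_samples``.
    """
    if not 0 < shift_samples < len(base):
        raise ValueError(
            f"shift must be in (0, {len(base)}) for overlap, got {shift_samples}"
        )
    if second_polarity not in ("+", "-"):
        raise ValueError(f"polarity must be '+' or '-', got {second_polarity!r}")
    if second_scale <= 0:
        raise ValueError("second_scale must be positive")
    second = np.abs(base.samples) * second_scale
    if second_polarity == "-":
        second = -second
    out = np.zeros(len(base) + shift_samples)
    out[: len(base)] += base.samples
    out[shift_samples:] += second
    base_sign = "+" if base.samples[base.apex_offset] >= 0 else "-"
    polarity = base_sign if second_polarity == base_sign else "biphasic"
    return WaveTemplate(
        samples=out,
        class_id=class_id or f"cplx{base.class_id}{second_polarity}",
        polarity=polarity,
        peak_amplitude_uv=float(np.max(np.abs(out))),
    )


def default_template_set(n_samples: int = 20) -> dict[str, WaveTemplate]:
    """The five default waveform classes.

    A: +80 uV triangle, B: -80 uV triangle, C: +45 uV triangle,
    D: two same-polarity triangles (70 and 45.5 uV) shifted 0.4 ms,
    E: biphasic complex (+70 then -45.5 uV) shifted 0.4 ms.
    The second lobe of each complex is scaled to 0.65 so every event has a
    single well-defined tallest peak (see docs/methods.md).
    """
    shift = n_samples // 2  # 0.4 ms at 25 kHz
    base70 = make_triangle_template(70.0, "+", n_samples)
    return {
        "A": make_triangle_template(80.0, "+", n_samples, class_id="A"),
        "B": make_triangle_template(80.0, "-", n_samples, class_id="B"),
        "C": make_triangle_template(45.0, "+", n_samples, class_id="C"),
        "D": make_complex_template(base70, shift, "+", second_scale=0.65, class_id="D"),
        "E": make_complex_template(base70, shift, "-", second_scale=0.65, class_id="E"),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic recording.

    Defaults follow the reference simulation: 60 s at 25 kHz, 600 events
    drawn uniformly over five classes, band-limited Gaussian noise
    (150-2500 Hz) mixed at exactly 5 dB SNR.
    """

    duration_s: float = 60.0
    fs_hz: float = 25_000.0
    n_events: int = 600
    class_mix: dict[str, float] | None = None  # None -> uniform over classes
    snr_db: float = 5.0
    noise_band: tuple[float, float] = (150.0, 2500.0)
    min_separation_ms: float = 5.0
    seed: int = 0
    template_samples: int = 20

    def __post_init__(self) -> None:
        self.noise_band = tuple(self.noise_band)  # normalize (YAML gives lists)
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.noise_band[1] >= self.fs_hz / 2:
            raise ValueError("noise band upper edge must be below Nyquist")
        if self.n_events * self.min_separation_ms / 1000.0 > self.duration_s:
            raise ValueError(
                "infeasible packing: n_events x min_separation exceeds duration"
            )
        if self.class_mix is not None:
            p = np.array(list(self.class_mix.values()), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("class_mix must be non-negative and sum to 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    @property
    def min_separation_samples(self) -> int:
        return int(round(self.min_separation_ms * 1e-3 * self.fs_hz))


TRUTH_COLUMNS = ["event_index", "time_s", "class_id", "peak_amplitude_uv", "polarity"]


def _draw_event_positions(
    rng: np.random.Generator, n_events: int, lo: int, hi: int, min_sep: int
) -> np.ndarray:
    """Uniform random peak positions with rejection to enforce separation."""
    if n_events == 0:
        return np.array([], dtype=int)
    if hi <= lo:
        raise ValueError("trace too short for the template length")
    positions: list[int] = []
    attempts = 0
    max_attempts = 2000 * n_events
    while len(positions) < n_events:
        if attempts > max_attempts:
            raise ValueError(
                "could not place events at the requested separation; "
                "reduce n_events or min_separation"
            )
        attempts += 1
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - p) >= min_sep for p in positions):
            positions.append(cand)
    return np.sort(np.array(positions, dtype=int))


def generate_clean_signal(
    config: SimulationConfig,
    templates: dict[str, WaveTemplate] | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Noise-free trace with exactly ``n_events`` template insertions.

    Events are placed uniformly at random with rejection so that tallest
    peaks are at least ``min_separation_ms`` apart; each overlapped complex
    counts as a single event.  Returns the trace and the ground-truth table
    (sorted by sample index of the tallest peak).
    """
    rng = np.random.default_rng(config.seed)
    templates = templates or default_template_set(config.template_samples)
    names = sorted(templates)
    if config.class_mix is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        probs = np.array([config.class_mix.get(n, 0.0) for n in names], dtype=float)
    trace = np.zeros(config.n_samples)
    max_len = max(len(t) for t in templates.values())
    # peak positions, kept clear of the edges so full templates always fit
    margin = max_len + 1
    peaks = _draw_event_positions(
        rng,
        config.n_events,
        margin,
        config.n_samples - margin,
        config.min_separation_samples,
    )
    labels = rng.choice(len(names), size=config.n_events, p=probs)
    rows = []
    for peak, lab in zip(peaks, labels):
        t = templates[names[lab]]
        start = peak - t.apex_offset
        trace[start : start + len(t)] += t.samples
        rows.append(
            {
                "event_index": int(peak),
                "time_s": peak / config.fs_hz,
                "class_id": t.class_id,
                "peak_amplitude_uv": t.peak_amplitude_uv,
                "polarity": "+" if t.samples[t.apex_offset] >= 0 else "-",
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return Recording(trace, config.fs_hz, channel_id="sim"), truth


def generate_bandlimited_noise(
    n_samples: int,
    fs_hz: float,
    band: tuple[float, float] = (150.0, 2500.0),
    seed: int | np.random.Generator = 0,
    order: int = 2,
) -> np.ndarray:
    """White Gaussian noise, Butterworth band-pass filtered and normalized
    to unit RMS."""
    if not 0 < band[0] < band[1] < fs_hz / 2:
        raise ValueError(f"band {band} outside (0, Nyquist) for fs={fs_hz}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    sos = signal.butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    filtered = signal.sosfilt(sos, white)
    rms = np.sqrt(np.mean(filtered**2))
    if rms == 0:
        raise ValueError("degenerate noise (zero power)")
    return filtered / rms


def measure_snr(clean: np.ndarray, noise_component: np.ndarray) -> float:
    """SNR in dB: 20*log10(RMS(clean)/RMS(noise))."""
    clean = np.asarray(clean, dtype=float)
    noise_component = np.asarray(noise_component, dtype=float)
    if clean.size != noise_component.size:
        raise ValueError("length mismatch")
    p_noise = np.mean(noise_component**2)
    if p_noise == 0:
        raise ValueError("zero-power noise: SNR undefined")
    p_clean = np.mean(clean**2)
    return float(10.0 * np.log10(p_clean / p_noise))


def noise_scale_for_snr(clean: np.ndarray, noise: np.ndarray, snr_db: float) -> float:
    """Scale factor alpha such that clean vs alpha*noise has exactly snr_db."""
    p_clean = np.mean(np.asarray(clean, dtype=float) ** 2)
    p_noise = np.mean(np.asarray(noise, dtype=float) ** 2)
    if p_clean == 0:
        raise ValueError("zero-power clean signal: SNR undefined")
    if p_noise == 0:
        raise ValueError("zero-power noise")
    return float(np.sqrt(p_clean / p_noise) * 10.0 ** (-snr_db / 20.0))


def mix_at_snr(clean: Recording, noise: np.ndarray, snr_db: float) -> Recording:
    """Add noise to a clean trace, scaled for an exact SNR in dB."""
    noise = np.asarray(noise, dtype=float)
    if noise.size != clean.n_samples:
        raise ValueError("length mismatch")
    alpha = noise_scale_for_snr(clean.samples, noise, snr_db)
    return clean.with_samples(clean.samples + alpha * noise)


@dataclass
class SimulationResult:
    """A complete simulated recording with its decomposition and truth."""

    recording: Recording  # clean + scaled noise
    clean: Recording
    noise: np.ndarray  # the scaled noise component actually added
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def snr_db(self) -> float:
        return measure_snr(self.clean.samples, self.noise)


def simulate(
    config: SimulationConfig | None = None,
    templates: dict[str, WaveTemplate] | None = None,
) -> SimulationResult:
    """Run the full generator: clean signal, noise, exact-SNR mix."""
    config = config or SimulationConfig()
    clean, truth = generate_clean_signal(config, templates)
    # decorrelate the noise stream from event placement
    noise_seed = (int(config.seed) * 2_654_435_761 + 1) % (2**31)
    noise = generate_bandlimited_noise(
        config.n_samples, config.fs_hz, config.noise_band, seed=noise_seed
    )
    if config.n_events == 0:
        raise ValueError("cannot set an SNR for a signal with no events")
    alpha = noise_scale_for_snr(clean.samples, noise, config.snr_db)
    scaled = alpha * noise
    mixed = clean.with_samples(clean.samples + scaled)
    return SimulationResult(
        recording=mixed, clean=clean, noise=scaled, truth=truth, config=config
    )
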