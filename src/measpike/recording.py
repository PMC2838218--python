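"""The universal input container: a sampled single-channel voltage trace.

Amplitudes are in microvolts throughout the package; time is in seconds,
sample indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np


@dataclass
class Recording:
    """A single-channel extracellular voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in microvolts (float).
    fs_hz
        Sampling rate in Hz.
    channel_id
        Electrode/channel label.
    t0_s
        Time of the first sample, in seconds.
    """

    samples: np.ndarray
    fs_hz: float
    channel_id: str = "ch0"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording expects a 1-D sample vector")
        if not self.fs_hz > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        """Per-sample time stamps in seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))


# ---------------------------------------------------------------------------
# File formats: raw int16 + JSON sidecar, and HDF5.


def write_raw(rec: Recording, path: str | Path, gain_uv_per_count: float = 0.1) -> None:
    """Write a trace as signed 16-bit raw binary plus a JSON sidecar.

    The sidecar `<path>.json` records sampling rate, quantization gain and
    channel metadata so the binary is self-describing.
    """
    path = Path(path)
    counts = np.clip(
        np.round(rec.samples / gain_uv_per_count), -32768, 32767
    ).astype("<i2")
    counts.tofile(path)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "gain_uv_per_count": gain_uv_per_count,
        "n_channels": 1,
        "channel_ids": [rec.channel_id],
        "dtype": "int16",
        "t0_s": rec.t0_s,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_raw(path: str | Path) -> Recording:
    """Read a raw int16 trace written by :func:`write_raw`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    counts = np.fromfile(path, dtype="<i2")
    samples = counts.astype(float) * sidecar["gain_uv_per_count"]
    return Recording(
        samples=samples,
        fs_hz=sidecar["fs_hz"],
        channel_id=sidecar["channel_ids"][0],
        t0_s=sidecar.get("t0_s", 0.0),
    )


def write_hdf5(rec: Recording, path: str | Path, dataset: str = "samples") -> None:
    """Write a trace to HDF5 (float microvolts, metadata as attributes)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=rec.samples)
        d.attrs["fs_hz"] = rec.fs_hz
        d.attrs["channel_id"] = rec.channel_id
        d.attrs["t0_s"] = rec.t0_s
        d.attrs["units"] = "uV"


def read_hdf5(path: str | Path, dataset: str = "samples") -> Recording:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        return Recording(
            samples=d[...],
            fs_hz=float(d.attrs["fs_hz"]),
            channel_id=str(d.attrs.get("channel_id", "ch0")),
            t0_s=float(d.attrs.get("t0_s", 0.0)),
        )
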