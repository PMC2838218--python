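"""End-to-end orchestration: simulate -> filter -> detect -> sort -> evaluate.

Every run writes its resolved configuration and a JSON report beside the
per-stage artifacts, so any stage can be re-run from files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import recording as rio
from .detect import (
    detect_threshold_crossings,
    events_to_frame,
    extract_waveforms,
    validate_events,
)
from .estimators import make_estimator, thresholds_to_frame
from .evaluate import MatchConfig, screen_detector
from .preprocess import bandpass_filter
from .recording import Recording
from .sort import SortingConfig, labels_to_frame, reconstruct_signal, sort_waveforms
from .synthetic import SimulationConfig, simulate

log = logging.getLogger("measpike")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_path: str | None = None  # read a trace instead of simulating
    truth_path: str | None = None
    estimator: str = "adabandflt"
    multiplier: float | None = None
    low_hz: float = 150.0
    high_hz: float = 2500.0
    filter_order: int = 2
    zero_phase: bool = True  # offline analysis; estimators stay causal-streaming
    validate: bool = True
    pre_init: str = "backfill"
    sorting: SortingConfig = field(default_factory=SortingConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)
    screen_validated: bool = False  # screening runs on unvalidated detections
    out_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "sorting" in d and d["sorting"] is not None:
            d["sorting"] = SortingConfig(**d["sorting"])
        if "matching" in d and d["matching"] is not None:
            d["matching"] = MatchConfig(**d["matching"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


def _load_input(config: PipelineConfig) -> tuple[Recording, pd.DataFrame | None]:
    if config.input_path is not None:
        p = Path(config.input_path)
        rec = rio.read_hdf5(p) if p.suffix in (".h5", ".hdf5") else rio.read_raw(p)
        truth = pd.read_csv(config.truth_path) if config.truth_path else None
        return rec, truth
    if config.simulation is None:
        raise ValueError("no input trace and simulation disabled")
    sim = simulate(dataclasses.replace(config.simulation, seed=config.seed))
    return sim.recording, sim.truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute detection -> PCA -> hierarchical classification.

    Returns the run report (counts, cluster summary, screening statistics
    when ground truth is available); writes artifacts if ``out_dir`` is
    set.
    """
    rec, truth = _load_input(config)
    log.info("input: %d samples at %g Hz", rec.n_samples, rec.fs_hz)

    filtered = bandpass_filter(
        rec, config.low_hz, config.high_hz, config.filter_order,
        zero_phase=config.zero_phase,
    )
    est = make_estimator(config.estimator, config.multiplier)
    thresholds = est.run(filtered)
    candidates = detect_threshold_crossings(filtered, thresholds, config.pre_init)
    log.info("windows: %d, candidates: %d", thresholds.n_windows, len(candidates))

    dropped = 0
    if config.validate:
        events, dropped = validate_events(candidates, filtered)
    else:
        events = candidates
    waveforms = extract_waveforms(filtered, events)
    log.info(
        "validated: %d, boundary-dropped: %d+%d",
        len(events), dropped, waveforms.n_dropped_boundary,
    )

    report: dict = {
        "estimator": est.name,
        "n_samples": rec.n_samples,
        "fs_hz": rec.fs_hz,
        "n_windows": int(thresholds.n_windows),
        "n_candidates": len(candidates),
        "n_validated": len(events) if config.validate else None,
        "n_dropped_boundary": int(dropped + waveforms.n_dropped_boundary),
        "n_waveforms": waveforms.n_waveforms,
    }

    pca = model = None
    if waveforms.n_waveforms >= 2:
        pca, model = sort_waveforms(waveforms, config.sorting)
        report["clusters"] = model.summary()
        n_acc = int(np.sum(model.accepted))
        log.info(
            "clusters: %d (%d accepted, %d noise-flagged)",
            model.n_clusters, n_acc, int(np.sum(model.is_noise)),
        )

    if truth is not None:
        screen_events = events if config.screen_validated else candidates
        sc = screen_detector(filtered, screen_events, truth, config.matching)
        report["n_truth_events"] = int(len(truth))
        report["screening"] = sc.as_dict()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        out.joinpath("config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        rio.write_hdf5(filtered, out / "filtered.h5")
        thresholds_to_frame(thresholds).to_csv(out / "thresholds.csv", index=False)
        events_to_frame(candidates).to_csv(out / "candidates.csv", index=False)
        events_to_frame(events).to_csv(out / "events.csv", index=False)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
        if model is not None:
            labels_to_frame(model, waveforms).to_csv(out / "labels.csv", index=False)
            import h5py

            with h5py.File(out / "waveforms.h5", "w") as f:
                d = f.create_dataset("waveforms", data=waveforms.waveforms)
                d.attrs["fs_hz"] = waveforms.fs_hz
                d.attrs["alignment_offset"] = waveforms.alignment_offset
                if model.mean_waveforms is not None:
                    f.create_dataset("cluster_means", data=model.mean_waveforms)
            recon = reconstruct_signal(model, waveforms, rec.n_samples)
            rio.write_hdf5(recon, out / "reconstruction.h5")
        out.joinpath("report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
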