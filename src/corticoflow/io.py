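"""Readers and writers for session and result files.

Session layout (BIDS-iEEG-like, documented column names):

* ``signal.npy`` + ``signal.json`` — channels × samples array with sampling
  rate, start time, and channel order (uncompressed array container);
* ``electrodes.tsv`` — name, region, hemisphere, x_mm, y_mm, z_mm;
* ``events.tsv`` — onset_s, stim_pair, intensity_ma, pulse_width_ms,
  block_id, block_kind;
* ``vigilance.tsv`` — onset_s, duration_s, state;
* ``ground_truth.json`` / ``ground_truth_trials.tsv`` — generator truth.

All times are seconds from recording start, windows in ms, coordinates in
mm, intensities in mA; unit suffixes are embedded in the column names.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import (
    BipolarRecording,
    ConnectionParams,
    GroundTruthNetwork,
    StimEvent,
    VigilanceTrack,
)

ELECTRODE_COLUMNS = ["name", "region", "hemisphere", "x_mm", "y_mm", "z_mm"]
EVENT_COLUMNS = ["onset_s", "stim_pair", "intensity_ma", "pulse_width_ms", "block_id", "block_kind"]
VIGILANCE_COLUMNS = ["onset_s", "duration_s", "state"]


def write_signal(path: Path, recording: BipolarRecording) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), recording.signal)
    meta = {
        "sampling_rate_hz": recording.sampling_rate,
        "start_time_s": recording.start_time,
        "n_channels": recording.n_channels,
        "n_samples": int(recording.signal.shape[1]),
        "channel_names": recording.channel_names,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_signal(path: Path, channel_table: pd.DataFrame) -> BipolarRecording:
    path = Path(path)
    sig = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["channel_names"] != list(channel_table["name"]):
        raise ValueError("channel order mismatch between signal sidecar and electrode table")
    return BipolarRecording(sig, meta["sampling_rate_hz"], channel_table, meta["start_time_s"])


def write_events(path: Path, events: Sequence[StimEvent]) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "stim_pair": e.stim_pair,
                "intensity_ma": e.intensity_ma,
                "pulse_width_ms": e.pulse_width_ms,
                "block_id": e.block_id,
                "block_kind": e.block_kind,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> list[StimEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        StimEvent(
            float(r.onset_s),
            str(r.stim_pair),
            float(r.intensity_ma),
            float(r.pulse_width_ms),
            int(r.block_id),
            str(r.block_kind),
        )
        for r in df.itertuples()
    ]


def write_vigilance(path: Path, track: VigilanceTrack) -> None:
    df = pd.DataFrame(
        [
            {"onset_s": start, "duration_s": end - start, "state": state}
            for start, end, state in track.segments
        ],
        columns=VIGILANCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_vigilance(path: Path) -> VigilanceTrack:
    df = pd.read_csv(path, sep="\t")
    return VigilanceTrack(
        [(float(r.onset_s), float(r.onset_s + r.duration_s), str(r.state)) for r in df.itertuples()]
    )


def write_network(dirpath: Path, network: GroundTruthNetwork) -> None:
    dirpath = Path(dirpath)
    network.electrodes[ELECTRODE_COLUMNS].to_csv(dirpath / "electrodes.tsv", sep="\t", index=False)
    conns = {
        f"{a}->{b}": {
            "true_probability": p.true_probability
            if not isinstance(p.true_probability, Mapping)
            else dict(p.true_probability),
            "latency_ms": p.latency_ms,
            "amplitude": p.amplitude,
            "sigmoid_midpoint_ma": p.sigmoid_midpoint_ma,
            "sigmoid_slope": p.sigmoid_slope,
            "state_gain": dict(p.state_gain),
            "amp_jitter_sigma": p.amp_jitter_sigma,
            "latency_jitter_ms": p.latency_jitter_ms,
        }
        for (a, b), p in network.connections.items()
    }
    (dirpath / "ground_truth.json").write_text(json.dumps(conns, indent=2, sort_keys=True))


def read_network(dirpath: Path) -> GroundTruthNetwork:
    dirpath = Path(dirpath)
    electrodes = pd.read_csv(dirpath / "electrodes.tsv", sep="\t")
    conns: dict[tuple[str, str], ConnectionParams] = {}
    gt_path = dirpath / "ground_truth.json"
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        for key, d in raw.items():
            a, b = key.split("->")
            conns[(a, b)] = ConnectionParams(**d)
    return GroundTruthNetwork(electrodes, conns)


def write_session(
    dirpath: Path,
    recording: BipolarRecording,
    events: Sequence[StimEvent],
    vigilance: VigilanceTrack,
    network: GroundTruthNetwork | None = None,
    truth_table: pd.DataFrame | None = None,
) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    write_signal(dirpath / "signal", recording)
    recording.channel_table[ELECTRODE_COLUMNS].to_csv(
        dirpath / "electrodes.tsv", sep="\t", index=False
    )
    write_events(dirpath / "events.tsv", events)
    write_vigilance(dirpath / "vigilance.tsv", vigilance)
    if network is not None:
        write_network(dirpath, network)
    if truth_table is not None:
        truth_table.to_csv(dirpath / "ground_truth_trials.tsv", sep="\t", index=False)


def read_session(dirpath: Path) -> tuple[BipolarRecording, list[StimEvent], VigilanceTrack]:
    dirpath = Path(dirpath)
    electrodes = pd.read_csv(dirpath / "electrodes.tsv", sep="\t")
    recording = read_signal(dirpath / "signal", electrodes)
    events = read_events(dirpath / "events.tsv")
    vigilance = read_vigilance(dirpath / "vigilance.tsv")
    return recording, events, vigilance


def read_incidence_csv(path: Path) -> pd.DataFrame:
    """Labeled square incidence matrix from CSV (first column = area labels)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_incidence_csv(path: Path, incidence: pd.DataFrame) -> None:
    incidence.to_csv(path)
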