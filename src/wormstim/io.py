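"""Columnar text formats for traces, events, onsets and results.

Traces are CSV (time_s, ch1_v, ch2_v, artifact_v) with a YAML sidecar
carrying sampling rate, geometry and protocol; all event tables are plain
CSV.  Write-then-read round-trips reproduce values to full stored
precision.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .latency import PropagatedAP, ResponseRecord
from .models import (
    ElectrodeGeometry,
    LEUSSequenceSpec,
    RecordingTrace,
    StimulusEvent,
)
from .signal import DetectedAP, StimulusOnset
from .synthetic import GroundTruthLog


class SchemaError(ValueError):
    pass


# -- trace -----------------------------------------------------------------

TRACE_COLUMNS = ["time_s", "ch1_v", "ch2_v", "artifact_v"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yml")


def _protocol_to_dicts(protocol: list[StimulusEvent]) -> list[dict]:
    out = []
    for e in protocol:
        d = {
            "stimulus_id": e.stimulus_id,
            "modality": e.modality,
            "onset_s": e.onset_s,
            "region": e.region,
        }
        if e.leus is not None:
            d["leus"] = {
                "carrier_frequency_hz": e.leus.carrier_frequency_hz,
                "n_cycles": e.leus.n_cycles,
                "prf_hz": e.leus.prf_hz,
                "n_pulses": e.leus.n_pulses,
                "pressure_amplitude_pa": e.leus.pressure_amplitude_pa,
            }
        out.append(d)
    return out


def protocol_from_dicts(dicts: list[dict]) -> list[StimulusEvent]:
    events = []
    for d in dicts:
        leus = LEUSSequenceSpec(**d["leus"]) if d.get("leus") else None
        events.append(
            StimulusEvent(
                stimulus_id=int(d["stimulus_id"]),
                modality=d["modality"],
                onset_s=float(d["onset_s"]),
                region=d.get("region", "anterior"),
                leus=leus,
            )
        )
    return events


def write_trace(trace: RecordingTrace, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {
            "time_s": trace.times,
            "ch1_v": trace.channels["ch1"],
            "ch2_v": trace.channels["ch2"],
            "artifact_v": trace.channels["artifact"],
        }
    )
    # %.17g guarantees an exact float64 round trip through text
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "geometry": asdict(trace.geometry) if trace.geometry else None,
        "protocol": _protocol_to_dicts(trace.protocol),
    }
    _sidecar_path(csv_path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return csv_path


def read_trace(csv_path: str | Path) -> RecordingTrace:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing columns {missing}")
    t = frame["time_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise SchemaError(f"{csv_path}: non-monotone time at line {bad}")

    sidecar = _sidecar_path(csv_path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        fs = float(meta["sampling_rate_hz"])
        if len(t) > 1:
            dt = float(np.median(np.diff(t)))
            if abs(dt * fs - 1.0) > 1e-3:
                raise SchemaError(
                    f"{csv_path}: sampling rate {fs} Hz disagrees with time column "
                    f"step {dt:g} s"
                )
        geometry = (
            ElectrodeGeometry(
                electrode_spacing=meta["geometry"]["electrode_spacing"],
                anode_separation=meta["geometry"]["anode_separation"],
                stim_to_first_anode=meta["geometry"]["stim_to_first_anode"],
            )
            if meta.get("geometry")
            else None
        )
        protocol = protocol_from_dicts(meta.get("protocol", []))
    else:
        if len(t) < 2:
            raise SchemaError(f"{csv_path}: cannot infer sampling rate from one sample")
        fs = 1.0 / float(np.median(np.diff(t)))
        geometry = None
        protocol = []
    return RecordingTrace(
        sampling_rate=fs,
        channels={
            "ch1": frame["ch1_v"].to_numpy(),
            "ch2": frame["ch2_v"].to_numpy(),
            "artifact": frame["artifact_v"].to_numpy(),
        },
        geometry=geometry,
        protocol=protocol,
    )


# -- events and onsets -----------------------------------------------------

EVENT_COLUMNS = [
    "channel",
    "t_pos_s",
    "t_neg_s",
    "amplitude_v",
    "lobe_separation_s",
    "quality",
]


def write_events(events: list[DetectedAP], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "channel": e.channel_id,
                "t_pos_s": e.positive_peak_time,
                "t_neg_s": e.negative_peak_time,
                "amplitude_v": e.peak_amplitude,
                "lobe_separation_s": e.lobe_separation,
                "quality": e.quality_score,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_events(path: str | Path) -> list[DetectedAP]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    events = []
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        if row.t_neg_s <= row.t_pos_s:
            raise SchemaError(
                f"{path}: line {line}: negative lobe at {row.t_neg_s} does not "
                f"follow the positive lobe at {row.t_pos_s}"
            )
        events.append(
            DetectedAP(
                channel_id=str(row.channel),
                positive_peak_time=float(row.t_pos_s),
                negative_peak_time=float(row.t_neg_s),
                peak_amplitude=float(row.amplitude_v),
                lobe_separation=float(row.lobe_separation_s),
                quality_score=float(row.quality),
            )
        )
    return events


ONSET_COLUMNS = ["stimulus_id", "onset_time_s", "modality"]


def write_onsets(onsets: list[StimulusOnset], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "stimulus_id": o.stimulus_id,
                "onset_time_s": o.onset_time,
                "modality": o.modality or "",
            }
            for o in onsets
        ],
        columns=ONSET_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_onsets(path: str | Path) -> list[StimulusOnset]:
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    missing = [c for c in ONSET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    onsets = [
        StimulusOnset(
            stimulus_id=int(row.stimulus_id),
            onset_time=float(row.onset_time_s),
            modality=str(row.modality) or None,
        )
        for row in frame.itertuples(index=False)
    ]
    times = [o.onset_time for o in onsets]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise SchemaError(f"{path}: onset times must be strictly increasing")
    return onsets


# -- results ---------------------------------------------------------------


def write_ground_truth(log: GroundTruthLog, path: str | Path) -> Path:
    path = Path(path)
    log.events.to_csv(path, index=False)
    return path


def write_responses(records: list[ResponseRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "stimulus_id": r.stimulus_id,
                "modality": r.modality or "",
                "responded": r.responded,
                "ap_count": r.ap_count,
            }
            for r in records
        ],
        columns=["stimulus_id", "modality", "responded", "ap_count"],
    ).to_csv(path, index=False)
    return path


def write_aps(records: list[ResponseRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        for ap in r.aps:
            rows.append(
                {
                    "stimulus_id": r.stimulus_id,
                    "modality": r.modality or "",
                    "fiber": ap.fiber_class,
                    "velocity_mps": ap.instantaneous_velocity,
                    "dt_ms": None if ap.arrival_delay is None else ap.arrival_delay * 1e3,
                    "top_ms": None if ap.top is None else ap.top * 1e3,
                    "tog_ms": None if ap.tog is None else ap.tog * 1e3,
                    "tog_flagged": ap.tog_flagged,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "stimulus_id",
            "modality",
            "fiber",
            "velocity_mps",
            "dt_ms",
            "top_ms",
            "tog_ms",
            "tog_flagged",
        ],
    ).to_csv(path, index=False)
    return path
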