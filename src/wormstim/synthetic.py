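"""Synthetic multichannel recordings with ground-truth AP bookkeeping.

Renders each planted AP as a biphasic waveform on both bipolar channels
(positive lobe at anode passage, negative lobe at cathode passage) plus a
modality-specific stimulus artifact on a dedicated channel, and returns a
per-AP ground-truth log so downstream detection and latency estimation
can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    ESTIM,
    FIBER_CLASSES,
    MSTIM,
    USTIM,
    ElectrodeGeometry,
    FiberModel,
    RecordingTrace,
    ResponseModel,
    StimulusEvent,
)

GROUND_TRUTH_COLUMNS = [
    "stimulus_id",
    "modality",
    "fiber",
    "tog_s",
    "velocity_mps",
    "anode1_arrival_s",
    "anode2_arrival_s",
    "cathode1_arrival_s",
    "cathode2_arrival_s",
    "amplitude_v",
    "collision",
]

ARTIFACT_COLUMNS = ["stimulus_id", "modality", "peak_time_s"]

ESTIM_ARTIFACT_WIDTH_S = 2.0e-4
USTIM_TICK_WIDTH_S = 2.0e-4
MSTIM_RISE_S = 1.0e-3
MSTIM_DECAY_TAU_S = 5.0e-3


class CollisionError(RuntimeError):
    """Planted APs would overlap closer than one lobe width."""


@dataclass
class GroundTruthLog:
    """Per-AP and per-artifact bookkeeping for one simulated recording."""

    events: pd.DataFrame
    artifact_peaks: pd.DataFrame
    dropped_refractory: int = 0
    dropped_out_of_range: int = 0

    @property
    def n_aps(self) -> int:
        return len(self.events)

    @property
    def empty(self) -> bool:
        return self.events.empty


def _add_raised_cosine(
    x: np.ndarray, fs: float, t_peak: float, amplitude: float, width: float
) -> None:
    """Add a unit-peak raised-cosine lobe of full support ``width`` in place."""
    half = width / 2.0
    i0 = max(int(math.ceil((t_peak - half) * fs)), 0)
    i1 = min(int(math.floor((t_peak + half) * fs)), len(x) - 1)
    if i1 < i0:
        return
    t = np.arange(i0, i1 + 1) / fs
    x[i0 : i1 + 1] += amplitude * 0.5 * (1.0 + np.cos(np.pi * (t - t_peak) / half))


def _add_contact_artifact(
    x: np.ndarray,
    fs: float,
    t0: float,
    amplitude: float,
    rise: float = MSTIM_RISE_S,
    tau: float = MSTIM_DECAY_TAU_S,
) -> None:
    """Step-like contact transient: cosine rise to a peak at ``t0``, then decay."""
    i0 = max(int(math.ceil((t0 - rise) * fs)), 0)
    ipk = min(int(math.floor(t0 * fs)), len(x) - 1)
    if ipk >= i0:
        t = np.arange(i0, ipk + 1) / fs
        x[i0 : ipk + 1] += amplitude * 0.5 * (1.0 + np.cos(np.pi * (t - t0) / rise))
    j0 = ipk + 1
    j1 = min(int(math.floor((t0 + 6 * tau) * fs)), len(x) - 1)
    if j1 >= j0:
        t = np.arange(j0, j1 + 1) / fs
        x[j0 : j1 + 1] += amplitude * np.exp(-(t - t0) / tau)


def _render_artifact_into(
    x: np.ndarray, fs: float, event: StimulusEvent, amplitude: float
) -> None:
    if event.modality == ESTIM:
        _add_raised_cosine(x, fs, event.onset_s, amplitude, ESTIM_ARTIFACT_WIDTH_S)
    elif event.modality == MSTIM:
        _add_contact_artifact(x, fs, event.onset_s, amplitude)
    else:
        _add_raised_cosine(x, fs, event.onset_s, amplitude, USTIM_TICK_WIDTH_S)


def render_stimulus_artifact(
    event: StimulusEvent,
    sampling_rate: float,
    duration: float | None = None,
    amplitude: float = 0.02,
) -> np.ndarray:
    """Render one stimulus artifact into a fresh waveform.

    The positive peak of the returned waveform falls within one sample of
    the event onset (it is the downstream time reference).
    """
    if not (math.isfinite(sampling_rate) and sampling_rate > 0):
        raise ValueError(f"invalid sampling rate {sampling_rate!r}")
    if duration is None:
        duration = event.onset_s + 0.05
    n = int(round(duration * sampling_rate))
    x = np.zeros(n)
    _render_artifact_into(x, sampling_rate, event, amplitude)
    return x


def _as_fiber_map(fibers) -> Mapping[str, FiberModel]:
    if isinstance(fibers, Mapping):
        out = dict(fibers)
    else:
        out = {f.fiber_class: f for f in fibers}
    for cls in FIBER_CLASSES:
        if cls not in out:
            raise ValueError(f"missing fiber model for class {cls}")
    return out


def _as_response_map(response) -> Mapping[str, ResponseModel]:
    if isinstance(response, Mapping):
        return dict(response)
    return {response.modality: response}


def simulate_recording(
    protocol: Sequence[StimulusEvent],
    fibers,
    response,
    geometry: ElectrodeGeometry,
    noise_sd: float = 5.0e-5,
    sampling_rate: float = 40000.0,
    seed: int = 0,
    *,
    duration: float | None = None,
    lobe_width: float = 0.8e-3,
    artifact_amplitude: float = 0.02,
    estim_bleed_gain: float = 3.0,
    tail_s: float = 0.4,
    on_collision: str = "raise",
) -> tuple[RecordingTrace, GroundTruthLog]:
    """Simulate a two-pair bipolar recording of a stimulation protocol.

    Parameters
    ----------
    protocol
        Administered stimuli with strictly increasing onsets.
    fibers
        Mapping (or pair) of :class:`FiberModel`, one per fiber class.
    response
        A single :class:`ResponseModel` or a mapping ``modality -> model``
        covering every modality present in the protocol.
    noise_sd
        SD of additive white Gaussian noise on each bipolar channel, volts.
    on_collision
        ``"raise"`` (default) aborts when two planted APs land closer than
        one lobe width; ``"flag"`` marks the colliding log rows instead.

    Returns
    -------
    (RecordingTrace, GroundTruthLog)
        Identical inputs and seed give bitwise-identical outputs.
    """
    if sampling_rate < 10000:
        raise ValueError("sampling_rate must be >= 10 kHz")
    if not (math.isfinite(noise_sd) and noise_sd >= 0):
        raise ValueError("noise_sd must be non-negative and finite")
    if on_collision not in ("raise", "flag"):
        raise ValueError("on_collision must be 'raise' or 'flag'")
    _require_models_finite(lobe_width=lobe_width, artifact_amplitude=artifact_amplitude)
    onsets = [e.onset_s for e in protocol]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("protocol onsets must be strictly increasing")

    fiber_map = _as_fiber_map(fibers)
    response_map = _as_response_map(response)
    for event in protocol:
        if event.modality not in response_map:
            raise ValueError(f"no ResponseModel provided for modality {event.modality}")

    if duration is None:
        duration = (onsets[-1] + tail_s) if onsets else 1.0
    n = int(round(duration * sampling_rate))
    if n <= 0:
        raise ValueError("duration too short for the given sampling rate")
    ch1 = np.zeros(n)
    ch2 = np.zeros(n)
    art = np.zeros(n)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    art_rows: list[dict] = []
    stim_counter: dict[str, int] = {}
    last_arrival: dict[str, float] = {}
    dropped_refractory = 0
    dropped_range = 0
    max_amp = max(f.peak_amplitude for f in fiber_map.values())

    for event in protocol:
        model = response_map[event.modality]
        _render_artifact_into(art, sampling_rate, event, artifact_amplitude)
        if event.modality == ESTIM and estim_bleed_gain > 0:
            # the electrical pulse couples into the recording electrodes
            bleed = estim_bleed_gain * max_amp
            _add_raised_cosine(ch1, sampling_rate, event.onset_s, bleed, ESTIM_ARTIFACT_WIDTH_S)
            _add_raised_cosine(ch2, sampling_rate, event.onset_s, bleed, ESTIM_ARTIFACT_WIDTH_S)
        art_rows.append(
            {
                "stimulus_id": event.stimulus_id,
                "modality": event.modality,
                "peak_time_s": event.onset_s,
            }
        )

        k = stim_counter.get(event.modality, 0)
        stim_counter[event.modality] = k + 1
        p = model.success_probability(event.leus)
        if p <= 0.0 or rng.random() >= p:
            continue

        for fiber_class in model.responding_fibers(rng):
            fib = fiber_map[fiber_class]
            for tog in model.sample_togs(fiber_class, k, rng, event.leus):
                velocity = fib.sample_velocity(rng)
                amplitude = fib.sample_amplitude(rng)
                anode1 = event.onset_s + tog + geometry.stim_to_first_anode / velocity
                prev = last_arrival.get(fiber_class)
                if prev is not None and abs(anode1 - prev) < fib.refractory_period:
                    dropped_refractory += 1
                    continue
                cathode1 = anode1 + geometry.anode_cathode_separation / velocity
                anode2 = anode1 + geometry.anode_separation / velocity
                cathode2 = anode2 + geometry.anode_cathode_separation / velocity
                if cathode2 + lobe_width / 2 >= duration or anode1 < lobe_width / 2:
                    dropped_range += 1
                    continue
                last_arrival[fiber_class] = anode1
                _add_raised_cosine(ch1, sampling_rate, anode1, amplitude, lobe_width)
                _add_raised_cosine(ch1, sampling_rate, cathode1, -amplitude, lobe_width)
                _add_raised_cosine(ch2, sampling_rate, anode2, amplitude, lobe_width)
                _add_raised_cosine(ch2, sampling_rate, cathode2, -amplitude, lobe_width)
                rows.append(
                    {
                        "stimulus_id": event.stimulus_id,
                        "modality": event.modality,
                        "fiber": fiber_class,
                        "tog_s": tog,
                        "velocity_mps": velocity,
                        "anode1_arrival_s": anode1,
                        "anode2_arrival_s": anode2,
                        "cathode1_arrival_s": cathode1,
                        "cathode2_arrival_s": cathode2,
                        "amplitude_v": amplitude,
                        "collision": False,
                    }
                )

    events_df = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    n_collisions = _mark_collisions(events_df, lobe_width)
    if n_collisions and on_collision == "raise":
        raise CollisionError(
            f"{n_collisions} planted APs overlap closer than one lobe width "
            f"({lobe_width * 1e3:.2f} ms); rerun with on_collision='flag' to keep them"
        )

    if noise_sd > 0:
        ch1 += rng.normal(0.0, noise_sd, n)
        ch2 += rng.normal(0.0, noise_sd, n)

    trace = RecordingTrace(
        sampling_rate=sampling_rate,
        channels={"ch1": ch1, "ch2": ch2, "artifact": art},
        geometry=geometry,
        protocol=list(protocol),
    )
    log = GroundTruthLog(
        events=events_df,
        artifact_peaks=pd.DataFrame(art_rows, columns=ARTIFACT_COLUMNS),
        dropped_refractory=dropped_refractory,
        dropped_out_of_range=dropped_range,
    )
    return trace, log


def _mark_collisions(events: pd.DataFrame, lobe_width: float) -> int:
    """Flag pairs of APs whose anode arrivals are closer than one lobe width."""
    if len(events) < 2:
        return 0
    order = np.argsort(events["anode1_arrival_s"].to_numpy())
    arrivals = events["anode1_arrival_s"].to_numpy()[order]
    too_close = np.diff(arrivals) < lobe_width
    flags = np.zeros(len(events), dtype=bool)
    for i, close in enumerate(too_close):
        if close:
            flags[order[i]] = True
            flags[order[i + 1]] = True
    events["collision"] = flags
    return int(flags.sum())


def _require_models_finite(**named: float) -> None:
    for name, value in named.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")
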