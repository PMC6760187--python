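"""Cross-channel AP matching, fiber classification, and latency decomposition.

The arrival delay of an AP is split into a propagation term (axonal
distance over the trial-mean conduction velocity of its fiber class) and
a generation term (the remainder), the quantity that localises where the
response was initiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import LGF, MGF, UNKNOWN, ElectrodeGeometry
from .signal import DetectedAP, StimulusOnset

DEFAULT_VELOCITY_WINDOW = (3.0, 30.0)
DEFAULT_VELOCITY_BOUNDARY = 12.0
DEFAULT_RESPONSE_WINDOW = 0.2


@dataclass
class PropagatedAP:
    """One AP matched across both recording sites."""

    ch1_event: DetectedAP
    ch2_event: DetectedAP
    instantaneous_velocity: float
    fiber_class: str = UNKNOWN
    stimulus_id: int | None = None
    arrival_delay: float | None = None
    top: float | None = None
    tog: float | None = None
    tog_flagged: bool = False

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.ch1_event.peak_amplitude + self.ch2_event.peak_amplitude)


@dataclass
class MatchResult:
    pairs: list[PropagatedAP]
    unmatched_ch1: list[DetectedAP]
    unmatched_ch2: list[DetectedAP]


@dataclass
class ResponseRecord:
    """Per-stimulus roll-up of the matched APs."""

    stimulus_id: int
    modality: str | None
    onset_time: float
    aps: list[PropagatedAP] = field(default_factory=list)

    @property
    def ap_count(self) -> int:
        return len(self.aps)

    @property
    def responded(self) -> bool:
        return self.ap_count >= 1


def match_across_channels(
    events_ch1: list[DetectedAP],
    events_ch2: list[DetectedAP],
    geometry: ElectrodeGeometry,
    velocity_window: tuple[float, float] = DEFAULT_VELOCITY_WINDOW,
) -> MatchResult:
    """Greedy one-to-one pairing of events across the two recording sites.

    A pair is valid iff the velocity implied by the anode separation and
    the positive-peak time difference lies inside ``velocity_window``.
    Events are consumed in time order and used at most once; whatever
    cannot be paired is reported, not dropped silently.
    """
    if geometry is None:
        raise ValueError("electrode geometry is required for cross-channel matching")
    v_lo, v_hi = velocity_window
    if not 0 < v_lo < v_hi:
        raise ValueError("velocity_window must be an increasing positive pair")
    sep = geometry.anode_separation
    max_dt = sep / v_lo
    min_dt = sep / v_hi

    ch1 = sorted(events_ch1, key=lambda e: e.positive_peak_time)
    ch2 = sorted(events_ch2, key=lambda e: e.positive_peak_time)
    used2 = [False] * len(ch2)
    pairs: list[PropagatedAP] = []
    unmatched1: list[DetectedAP] = []

    j0 = 0
    for e1 in ch1:
        t1 = e1.positive_peak_time
        match_j = None
        for j in range(j0, len(ch2)):
            if used2[j]:
                continue
            dt = ch2[j].positive_peak_time - t1
            if dt < min_dt:
                continue
            if dt > max_dt:
                break
            match_j = j
            break
        if match_j is None:
            unmatched1.append(e1)
            continue
        used2[match_j] = True
        dt = ch2[match_j].positive_peak_time - t1
        pairs.append(
            PropagatedAP(
                ch1_event=e1,
                ch2_event=ch2[match_j],
                instantaneous_velocity=sep / dt,
            )
        )
    unmatched2 = [e for e, used in zip(ch2, used2) if not used]
    return MatchResult(pairs=pairs, unmatched_ch1=unmatched1, unmatched_ch2=unmatched2)


def classify_fiber(
    ap: PropagatedAP,
    amplitude_boundary: float | None = None,
    velocity_boundary: float = DEFAULT_VELOCITY_BOUNDARY,
) -> str:
    """Assign a fiber class from velocity (and, if given, amplitude).

    Velocity at or above the boundary votes for the faster class (MGF),
    below for LGF.  When an amplitude boundary is supplied, the two
    criteria must agree; a conflict yields ``UNKNOWN``.
    """
    v_class = MGF if ap.instantaneous_velocity >= velocity_boundary else LGF
    if amplitude_boundary is None:
        return v_class
    a_class = MGF if ap.amplitude >= amplitude_boundary else LGF
    return v_class if v_class == a_class else UNKNOWN


def compute_top(axonal_distance: float, mean_velocity: float) -> float:
    """Time of propagation: distance from stimulation site to the first anode
    divided by the mean conduction velocity."""
    if not (math.isfinite(axonal_distance) and axonal_distance > 0):
        raise ValueError(f"axonal_distance must be positive, got {axonal_distance!r}")
    if not (math.isfinite(mean_velocity) and mean_velocity > 0):
        raise ValueError(f"mean_velocity must be positive, got {mean_velocity!r}")
    return axonal_distance / mean_velocity


def compute_tog(arrival_delay: float, top: float) -> float:
    """Time of generation: arrival delay minus time of propagation.

    May come out negative (physiologically implausible); callers flag such
    values rather than clipping them.
    """
    if not math.isfinite(arrival_delay):
        raise ValueError("arrival_delay must be finite")
    if not (math.isfinite(top) and top >= 0):
        raise ValueError("top must be non-negative and finite")
    return arrival_delay - top


def assemble_responses(
    onsets: list[StimulusOnset],
    paps: list[PropagatedAP],
    response_window: float = DEFAULT_RESPONSE_WINDOW,
) -> tuple[list[ResponseRecord], list[PropagatedAP]]:
    """Group matched APs under the most recent stimulus onset.

    Each AP is assigned to the latest onset no more than ``response_window``
    seconds before its first-anode positive peak; the arrival delay is set
    in the same step.  APs preceding the first onset or falling outside
    every window are returned as unassigned.
    """
    if response_window <= 0:
        raise ValueError("response_window must be positive")
    ordered = sorted(onsets, key=lambda o: o.onset_time)
    records = [
        ResponseRecord(stimulus_id=o.stimulus_id, modality=o.modality, onset_time=o.onset_time)
        for o in ordered
    ]
    onset_times = np.array([o.onset_time for o in ordered])
    unassigned: list[PropagatedAP] = []
    for pap in sorted(paps, key=lambda p: p.ch1_event.positive_peak_time):
        t = pap.ch1_event.positive_peak_time
        i = int(np.searchsorted(onset_times, t, side="right")) - 1
        if i < 0 or t - onset_times[i] > response_window:
            unassigned.append(pap)
            continue
        pap.stimulus_id = records[i].stimulus_id
        pap.arrival_delay = t - onset_times[i]
        records[i].aps.append(pap)
    return records, unassigned


def finalize_latencies(
    records: list[ResponseRecord],
    geometry: ElectrodeGeometry,
    velocity_boundary: float = DEFAULT_VELOCITY_BOUNDARY,
    amplitude_boundary: float | None = None,
) -> dict[str, float]:
    """Classify fibers, estimate trial-mean velocities, and fill TOP/TOG.

    The propagation time uses the trial-level mean of the instantaneous
    velocities of the AP's own fiber class.  Negative generation times are
    flagged and left in place for diagnostics.  Returns the per-class mean
    velocities.
    """
    all_aps = [ap for r in records for ap in r.aps]
    for ap in all_aps:
        ap.fiber_class = classify_fiber(ap, amplitude_boundary, velocity_boundary)
    mean_velocity: dict[str, float] = {}
    for cls in (MGF, LGF):
        velocities = [ap.instantaneous_velocity for ap in all_aps if ap.fiber_class == cls]
        if velocities:
            mean_velocity[cls] = float(np.mean(velocities))
    for ap in all_aps:
        if ap.fiber_class not in mean_velocity or ap.arrival_delay is None:
            continue
        ap.top = compute_top(geometry.stim_to_first_anode, mean_velocity[ap.fiber_class])
        ap.tog = compute_tog(ap.arrival_delay, ap.top)
        ap.tog_flagged = ap.tog < 0
    return mean_velocity


def success_rate(records: list[ResponseRecord]) -> float:
    """Fraction of administered stimuli that evoked at least one AP."""
    if not records:
        raise ValueError("success_rate requires at least one response record")
    return sum(r.responded for r in records) / len(records)
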