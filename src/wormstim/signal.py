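"""Band-pass filtering, stimulus-onset detection and biphasic AP detection."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .models import ESTIM, MSTIM, USTIM, RecordingTrace

log = logging.getLogger(__name__)

#: default artifact blanking window after a stimulus onset, per modality (s).
DEFAULT_BLANKING = {ESTIM: 2.0e-3, MSTIM: 0.0, USTIM: 0.0}

#: positive-to-negative lobe separation accepted as one biphasic AP (s);
#: covers a 1 cm anode-cathode gap at roughly 3-33 m/s.
DEFAULT_LOBE_WINDOW = (0.3e-3, 3.0e-3)


@dataclass(frozen=True)
class StimulusOnset:
    stimulus_id: int
    onset_time: float
    modality: str | None = None


@dataclass(frozen=True)
class DetectedAP:
    """One biphasic AP event on one channel."""

    channel_id: str
    positive_peak_time: float
    negative_peak_time: float
    peak_amplitude: float
    lobe_separation: float
    quality_score: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.negative_peak_time <= self.positive_peak_time:
            raise ValueError("negative lobe must follow the positive lobe")


def bandpass_filter(
    trace: RecordingTrace,
    low: float = 120.0,
    high: float = 1200.0,
    order: int = 4,
    channel_ids: tuple[str, ...] = ("ch1", "ch2"),
) -> RecordingTrace:
    """Zero-phase Butterworth band-pass of the bipolar channels.

    Applied forward-backward so event peak times are not shifted.  The
    artifact channel is passed through untouched (its step-like shapes are
    the onset references and must not be differentiated away).
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz); "
            f"got ({low}, {high})"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=trace.sampling_rate, output="sos")
    padlen = 3 * (2 * len(sos) + 1)
    if trace.n_samples <= padlen:
        raise ValueError(
            f"trace too short for filter warm-up ({trace.n_samples} <= {padlen} samples)"
        )
    channels = {}
    for cid, x in trace.channels.items():
        channels[cid] = sosfiltfilt(sos, x) if cid in channel_ids else x.copy()
    return trace.copy_with_channels(channels)


def detect_stimulus_onsets(
    trace: RecordingTrace,
    min_height: float | None = None,
    dead_time: float = 5.0e-3,
    abs_floor: float = 1.0e-6,
) -> list[StimulusOnset]:
    """One onset per artifact-channel event, at the positive artifact peak."""
    if "artifact" not in trace.channels:
        raise ValueError("trace has no artifact channel")
    art = trace.channels["artifact"]
    fs = trace.sampling_rate
    if art.size == 0 or art.max() < abs_floor:
        idx = np.array([], dtype=int)
    else:
        height = min_height if min_height is not None else 0.5 * art.max()
        idx, _ = find_peaks(art, height=height, distance=max(int(round(dead_time * fs)), 1))

    declared = len(trace.protocol)
    if declared and len(idx) != declared:
        warnings.warn(
            f"protocol declares {declared} stimuli but {len(idx)} artifact "
            "onsets were detected",
            stacklevel=2,
        )
    by_order = trace.protocol if len(trace.protocol) == len(idx) else None
    onsets = []
    for rank, i in enumerate(idx):
        event = by_order[rank] if by_order else None
        onsets.append(
            StimulusOnset(
                stimulus_id=event.stimulus_id if event else rank,
                onset_time=i / fs,
                modality=event.modality if event else None,
            )
        )
    return onsets


def _robust_scale(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _refine_peak(x: np.ndarray, i: int, fs: float) -> float:
    """Sub-sample peak time by parabolic interpolation through 3 samples."""
    if i <= 0 or i >= len(x) - 1:
        return i / fs
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom == 0:
        return i / fs
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return (i + delta) / fs


def detect_aps(
    trace: RecordingTrace,
    threshold_k: float = 4.0,
    *,
    onsets: list[StimulusOnset] | None = None,
    blanking: dict[str, float] | None = None,
    lobe_window: tuple[float, float] = DEFAULT_LOBE_WINDOW,
    neg_frac: float = 0.4,
    dead_time: float = 1.0e-3,
    relative_floor: float = 0.05,
    channel_ids: tuple[str, ...] = ("ch1", "ch2"),
    saturation_v: float | None = None,
    return_diagnostics: bool = False,
):
    """Detect biphasic AP events on the (already band-passed) bipolar channels.

    A candidate is a positive excursion above ``threshold_k`` times the
    MAD-based baseline scale, followed within ``lobe_window`` by a negative
    excursion of comparable magnitude.  Candidates inside a per-modality
    blanking window after a stimulus onset are suppressed; unpaired lobes
    are discarded (and reported in the diagnostics table).

    Returns the events sorted by positive-peak time; with
    ``return_diagnostics=True`` also returns a DataFrame of suppressed and
    unpaired candidates.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    blanking = dict(DEFAULT_BLANKING, **(blanking or {}))
    fs = trace.sampling_rate
    w_lo, w_hi = lobe_window
    events: list[DetectedAP] = []
    diagnostics: list[dict] = []

    blank_spans: list[tuple[float, float]] = []
    for onset in onsets or []:
        span = blanking.get(onset.modality or "", 0.0)
        if span > 0:
            blank_spans.append((onset.onset_time, onset.onset_time + span))

    for cid in channel_ids:
        if cid not in trace.channels:
            continue
        x = trace.channels[cid]
        if x.size == 0:
            continue
        scale = _robust_scale(x)
        peak_abs = float(np.max(np.abs(x)))
        if peak_abs == 0.0:
            continue
        threshold = max(threshold_k * scale, relative_floor * peak_abs)
        distance = max(int(round(dead_time * fs)), 1)
        pos_idx, pos_props = find_peaks(x, height=threshold, distance=distance)
        neg_idx, neg_props = find_peaks(-x, height=neg_frac * threshold, distance=distance)
        neg_heights = neg_props["peak_heights"]
        used_neg = np.zeros(len(neg_idx), dtype=bool)

        # larger positive lobes claim their negative partner first
        for p in pos_idx[np.argsort(-x[pos_idx], kind="stable")]:
            tp = p / fs
            if any(lo < tp <= hi for lo, hi in blank_spans):
                diagnostics.append(
                    {"channel": cid, "time_s": tp, "reason": "blanked", "amplitude_v": x[p]}
                )
                continue
            lo_i = np.searchsorted(neg_idx, p + int(math.floor(w_lo * fs)), side="right")
            hi_i = np.searchsorted(neg_idx, p + int(math.ceil(w_hi * fs)), side="right")
            candidates = [
                j for j in range(lo_i, hi_i)
                if not used_neg[j]
                and neg_heights[j] >= neg_frac * x[p]
                and x[p] >= neg_frac * neg_heights[j]
            ]
            if not candidates:
                diagnostics.append(
                    {"channel": cid, "time_s": tp, "reason": "unpaired", "amplitude_v": x[p]}
                )
                continue
            j = max(candidates, key=lambda j: neg_heights[j])
            used_neg[j] = True
            tp = _refine_peak(x, p, fs)
            tn = _refine_peak(-x, int(neg_idx[j]), fs)
            pos_amp = float(x[p])
            neg_amp = float(neg_heights[j])
            saturated = bool(
                saturation_v is not None and max(pos_amp, neg_amp) >= saturation_v
            )
            events.append(
                DetectedAP(
                    channel_id=cid,
                    positive_peak_time=tp,
                    negative_peak_time=tn,
                    peak_amplitude=pos_amp,
                    lobe_separation=tn - tp,
                    quality_score=min(pos_amp, neg_amp) / max(pos_amp, neg_amp),
                    saturated=saturated,
                )
            )

    events.sort(key=lambda e: (e.positive_peak_time, e.channel_id))
    if diagnostics:
        log.debug("detect_aps: %d candidates suppressed or unpaired", len(diagnostics))
    if return_diagnostics:
        diag = pd.DataFrame(diagnostics, columns=["channel", "time_s", "reason", "amplitude_v"])
        return events, diag
    return events
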