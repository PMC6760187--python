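import numpy as np
import pytest

from wormstim import (
    RecordingTrace,
    bandpass_filter,
    detect_aps,
    detect_stimulus_onsets,
    periodic_protocol,
    simulate_recording,
)
from wormstim.models import MSTIM, StimulusEvent
from wormstim.signal import DetectedAP, StimulusOnset

FS = 40000.0


def _trace_from(x, artifact=None, fs=FS):
    n = len(x)
    return RecordingTrace(
        sampling_rate=fs,
        channels={
            "ch1": np.asarray(x, dtype=float),
            "ch2": np.zeros(n),
            "artifact": np.zeros(n) if artifact is None else np.asarray(artifact),
        },
    )


def _fft_amplitude(x, fs, freq):
    """Independent spectral-amplitude oracle via the DFT bin at ``freq``."""
    spectrum = np.fft.rfft(x * np.hanning(len(x)))
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return np.abs(spectrum[np.argmin(np.abs(freqs - freq))])


class TestBandpassFilter:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 600 * t)
        out = bandpass_filter(_trace_from(x)).channels["ch1"]
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.max(np.abs(out[mid])) == pytest.approx(1.0, rel=0.05)

    def test_drift_removed(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass_filter(_trace_from(x)).channels["ch1"]
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.max(np.abs(out[mid])) < 0.05
        # cross-check with an FFT measurement of the same attenuation
        assert _fft_amplitude(out, FS, 10.0) < 0.05 * _fft_amplitude(x, FS, 10.0)

    def test_zero_phase_keeps_planted_peak(self):
        from wormstim.synthetic import _add_raised_cosine

        x = np.zeros(int(FS))
        t0 = 0.5
        _add_raised_cosine(x, FS, t0, 1.0, 1.2e-3)
        out = bandpass_filter(_trace_from(x)).channels["ch1"]
        assert abs(np.argmax(out) / FS - t0) <= 1.0 / FS

    def test_invalid_band_edges(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError, match="band edges"):
            bandpass_filter(_trace_from(x), low=1200, high=120)
        with pytest.raises(ValueError, match="band edges"):
            bandpass_filter(_trace_from(x), low=120, high=30000)

    def test_too_short_trace(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(_trace_from(np.zeros(10)))

    def test_artifact_channel_untouched(self):
        art = np.zeros(int(FS))
        art[1000] = 1.0
        trace = _trace_from(np.zeros(int(FS)), artifact=art)
        out = bandpass_filter(trace)
        assert np.array_equal(out.channels["artifact"], art)


class TestDetectStimulusOnsets:
    def test_planted_onsets_recovered_within_one_sample(self, models):
        protocol = periodic_protocol(["MStim"], 20, region="posterior")
        trace, _ = simulate_recording(
            protocol, models.fibers, models.responses, models.geometry, seed=4
        )
        onsets = detect_stimulus_onsets(trace)
        assert len(onsets) == 20
        for onset, event in zip(onsets, protocol):
            assert abs(onset.onset_time - event.onset_s) <= 1.0 / FS
            assert onset.modality == MSTIM

    def test_flat_artifact_channel_gives_empty_list(self):
        trace = _trace_from(np.zeros(4000))
        assert detect_stimulus_onsets(trace) == []

    def test_two_artifacts_10ms_apart_not_merged(self):
        art = np.zeros(4000)
        art[1000] = 1.0
        art[1400] = 1.0  # 10 ms at 40 kHz
        trace = _trace_from(np.zeros(4000), artifact=art)
        onsets = detect_stimulus_onsets(trace)
        assert len(onsets) == 2

    def test_count_mismatch_warns(self, models):
        protocol = [StimulusEvent(0, MSTIM, 0.05, region="posterior")]
        trace = _trace_from(np.zeros(4000))
        trace.protocol = protocol
        with pytest.warns(UserWarning, match="declares 1"):
            assert detect_stimulus_onsets(trace) == []

    def test_missing_artifact_channel(self):
        trace = RecordingTrace(FS, {"ch1": np.zeros(100), "ch2": np.zeros(100)})
        with pytest.raises(ValueError, match="artifact"):
            detect_stimulus_onsets(trace)


class TestDetectAPs:
    def test_noiseless_recovery_exact(self, models, estim_noiseless):
        trace, log = estim_noiseless
        filtered = bandpass_filter(trace)
        onsets = detect_stimulus_onsets(filtered)
        events = detect_aps(filtered, onsets=onsets)
        for cid, col in (("ch1", "anode1_arrival_s"), ("ch2", "anode2_arrival_s")):
            detected = np.sort(
                [e.positive_peak_time for e in events if e.channel_id == cid]
            )
            truth = np.sort(log.events[col].to_numpy())
            assert len(detected) == len(truth)
            assert np.max(np.abs(detected - truth)) <= 1.0 / trace.sampling_rate

    def test_empty_trace_gives_empty_list(self):
        assert detect_aps(_trace_from(np.zeros(0))) == []

    def test_offset_invariance(self, models, estim_noiseless):
        trace, _ = estim_noiseless
        shifted = trace.copy_with_channels(
            {cid: x + 0.5 for cid, x in trace.channels.items()}
        )
        shifted.channels["artifact"] = trace.channels["artifact"].copy()
        ev1 = detect_aps(bandpass_filter(trace))
        ev2 = detect_aps(bandpass_filter(shifted))
        t1 = [e.positive_peak_time for e in ev1]
        t2 = [e.positive_peak_time for e in ev2]
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_no_detection_inside_blanking_window(self, models):
        protocol = periodic_protocol(["EStim"], 10, region="anterior")
        trace, _ = simulate_recording(
            protocol,
            models.fibers,
            models.responses["EStim"],
            models.geometry,
            noise_sd=5e-5,
            seed=8,
        )
        filtered = bandpass_filter(trace)
        onsets = detect_stimulus_onsets(filtered)
        events = detect_aps(filtered, threshold_k=2.0, onsets=onsets)
        for event in events:
            for onset in onsets:
                assert not (
                    onset.onset_time < event.positive_peak_time <= onset.onset_time + 2e-3
                )

    def test_lobe_separation_within_window(self, estim_noiseless):
        trace, _ = estim_noiseless
        events = detect_aps(bandpass_filter(trace))
        for e in events:
            assert 0.3e-3 <= e.lobe_separation <= 3e-3
            assert e.negative_peak_time > e.positive_peak_time

    def test_recall_small_scale(self, models):
        """Reduced version of the SNR-3 recall check (full size in acceptance)."""
        from wormstim.models import LGF, FiberModel, ResponseModel, TogDistribution

        amp = 0.6e-3
        fibers = {
            "MGF": models.fibers["MGF"],
            "LGF": FiberModel(LGF, 9.0, 0.074, amp, 0.0),
        }
        dist = TogDistribution(33e-3, 0.25)
        responder = ResponseModel(
            MSTIM, tog={"MGF": dist, "LGF": dist}, region="posterior"
        )
        protocol = periodic_protocol(["MStim"], 50, interval_s=0.3)
        trace, log = simulate_recording(
            protocol, fibers, responder, models.geometry, noise_sd=amp / 3, seed=5
        )
        filtered = bandpass_filter(trace)
        events = detect_aps(filtered, threshold_k=2.5)
        detected = np.array(
            [e.positive_peak_time for e in events if e.channel_id == "ch1"]
        )
        truth = log.events.anode1_arrival_s.to_numpy()
        recall = np.mean(
            [np.any(np.abs(detected - t) < 0.25e-3) for t in truth]
        )
        assert recall >= 0.95

    def test_doubling_sampling_rate_moves_peaks_less_than_100us(self, models):
        protocol = periodic_protocol(["EStim"], 5, region="anterior")
        times = {}
        for fs in (40000.0, 80000.0):
            trace, _ = simulate_recording(
                protocol,
                models.fibers,
                models.responses["EStim"],
                models.geometry,
                noise_sd=0.0,
                sampling_rate=fs,
                seed=1,
            )
            events = detect_aps(bandpass_filter(trace))
            times[fs] = np.sort(
                [e.positive_peak_time for e in events if e.channel_id == "ch1"]
            )
        assert len(times[40000.0]) == len(times[80000.0])
        assert np.max(np.abs(times[40000.0] - times[80000.0])) < 0.1e-3

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            detect_aps(_trace_from(np.zeros(100)), threshold_k=0.0)


class TestDetectedAP:
    def test_rejects_inverted_lobes(self):
        with pytest.raises(ValueError, match="follow"):
            DetectedAP("ch1", 0.2, 0.1, 1e-3, -0.1, 1.0)
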