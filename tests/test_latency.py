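import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormstim import (
    ElectrodeGeometry,
    assemble_responses,
    bandpass_filter,
    classify_fiber,
    compute_tog,
    compute_top,
    detect_aps,
    detect_stimulus_onsets,
    finalize_latencies,
    match_across_channels,
    periodic_protocol,
    simulate_recording,
    success_rate,
)
from wormstim.latency import PropagatedAP, ResponseRecord
from wormstim.models import LGF, MGF, MSTIM, UNKNOWN
from wormstim.signal import DetectedAP, StimulusOnset


def _event(cid, t_pos, amplitude=1e-3, sep=0.8e-3):
    return DetectedAP(cid, t_pos, t_pos + sep, amplitude, sep, 1.0)


def _pap(velocity, amplitude=1e-3, t=0.1):
    return PropagatedAP(
        ch1_event=_event("ch1", t, amplitude),
        ch2_event=_event("ch2", t + 0.02 / velocity, amplitude),
        instantaneous_velocity=velocity,
    )


class TestMatchAcrossChannels:
    def test_hand_checked_velocity(self):
        # 2 cm in 1.2 ms -> 16.7 m/s
        res = match_across_channels(
            [_event("ch1", 0.1000)], [_event("ch2", 0.1012)], ElectrodeGeometry()
        )
        assert len(res.pairs) == 1
        assert res.pairs[0].instantaneous_velocity == pytest.approx(0.02 / 0.0012)

    def test_zero_delay_rejected(self):
        res = match_across_channels(
            [_event("ch1", 0.1)], [_event("ch2", 0.1)], ElectrodeGeometry()
        )
        assert res.pairs == []
        assert len(res.unmatched_ch1) == 1
        assert len(res.unmatched_ch2) == 1

    def test_velocity_outside_window_rejected(self):
        # 2 cm in 20 ms -> 1 m/s, below the window
        res = match_across_channels(
            [_event("ch1", 0.1)], [_event("ch2", 0.12)], ElectrodeGeometry()
        )
        assert res.pairs == []

    def test_noiseless_synthetic_velocities_recovered(self, models):
        # higher sampling rate keeps per-AP quantization error well below 2%
        protocol = periodic_protocol(["EStim"], 5, interval_s=0.3, region="anterior")
        trace, log = simulate_recording(
            protocol,
            models.fibers,
            models.responses["EStim"],
            models.geometry,
            noise_sd=0.0,
            sampling_rate=100000.0,
            seed=6,
        )
        events = detect_aps(bandpass_filter(trace))
        res = match_across_channels(
            [e for e in events if e.channel_id == "ch1"],
            [e for e in events if e.channel_id == "ch2"],
            models.geometry,
        )
        assert len(res.pairs) == log.n_aps == 10
        recovered = np.sort([p.instantaneous_velocity for p in res.pairs])
        planted = np.sort(log.events.velocity_mps.to_numpy())
        assert np.max(np.abs(recovered - planted) / planted) < 0.02

    def test_requires_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            match_across_channels([], [], None)

    def test_empty_inputs(self):
        res = match_across_channels([], [], ElectrodeGeometry())
        assert res.pairs == []


class TestClassifyFiber:
    def test_paper_velocities(self):
        assert classify_fiber(_pap(16.6)) == MGF
        assert classify_fiber(_pap(9.0)) == LGF

    def test_boundary_belongs_to_faster_class(self):
        assert classify_fiber(_pap(12.0, amplitude=1e-3), amplitude_boundary=0.8e-3) == MGF

    def test_conflicting_criteria_give_unknown(self):
        assert (
            classify_fiber(_pap(16.6, amplitude=0.1e-3), amplitude_boundary=0.8e-3)
            == UNKNOWN
        )


class TestComputeTopTog:
    def test_top_worked_examples(self):
        assert round(compute_top(0.084, 16.6) * 1e3, 1) == 5.1
        assert round(compute_top(0.084, 9.0) * 1e3, 1) == 9.3

    def test_top_identity(self):
        assert compute_top(7.5, 7.5) == 1.0

    def test_top_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_top(0.0, 16.6)
        with pytest.raises(ValueError):
            compute_top(0.084, -1.0)

    def test_tog_worked_examples(self):
        assert round(compute_tog(6.4, 5.1), 1) == 1.3
        assert round(compute_tog(42.2, 9.2), 1) == 33.0

    def test_tog_zero(self):
        assert compute_tog(5.0, 5.0) == 0.0

    def test_tog_may_be_negative(self):
        assert compute_tog(1.0, 2.0) == -1.0


class TestAssembleResponses:
    def test_no_aps_gives_all_nonresponders(self):
        onsets = [StimulusOnset(i, 0.5 * i + 0.5, MSTIM) for i in range(20)]
        records, unassigned = assemble_responses(onsets, [])
        assert len(records) == 20
        assert all(not r.responded for r in records)
        assert unassigned == []

    def test_window_boundary(self):
        onsets = [StimulusOnset(0, 1.0, MSTIM)]
        inside = _pap(10.0, t=1.0 + 0.199)
        outside = _pap(10.0, t=1.0 + 0.250)
        records, unassigned = assemble_responses(onsets, [inside, outside], 0.2)
        assert records[0].ap_count == 1
        assert unassigned == [outside]
        assert inside.arrival_delay == pytest.approx(0.199)

    def test_ap_before_first_onset_unassigned(self):
        onsets = [StimulusOnset(0, 1.0, MSTIM)]
        early = _pap(10.0, t=0.5)
        _, unassigned = assemble_responses(onsets, [early])
        assert unassigned == [early]

    def test_synthetic_counts_match_ground_truth(self, models):
        protocol = periodic_protocol(["UStim"], 30, region="posterior")
        trace, log = simulate_recording(
            protocol,
            models.fibers,
            models.responses,
            models.geometry,
            noise_sd=0.0,
            seed=17,
        )
        filtered = bandpass_filter(trace)
        onsets = detect_stimulus_onsets(filtered)
        events = detect_aps(filtered, onsets=onsets)
        res = match_across_channels(
            [e for e in events if e.channel_id == "ch1"],
            [e for e in events if e.channel_id == "ch2"],
            models.geometry,
        )
        records, _ = assemble_responses(onsets, res.pairs)
        truth_counts = log.events.groupby("stimulus_id").size()
        for record in records:
            assert record.ap_count == truth_counts.get(record.stimulus_id, 0)


class TestFinalizeLatencies:
    def test_identity_dt_equals_top_plus_tog(self, models):
        protocol = periodic_protocol(["MStim"], 40, region="posterior")
        trace, _ = simulate_recording(
            protocol, models.fibers, models.responses, models.geometry, seed=9
        )
        filtered = bandpass_filter(trace)
        onsets = detect_stimulus_onsets(filtered)
        events = detect_aps(filtered, onsets=onsets)
        res = match_across_channels(
            [e for e in events if e.channel_id == "ch1"],
            [e for e in events if e.channel_id == "ch2"],
            models.geometry,
        )
        records, _ = assemble_responses(onsets, res.pairs)
        finalize_latencies(records, models.geometry)
        checked = 0
        for record in records:
            for ap in record.aps:
                if ap.tog is not None:
                    assert ap.arrival_delay == ap.top + ap.tog  # exact, no rounding
                    checked += 1
        assert checked > 10

    def test_noiseless_classification_matches_truth(self, models, estim_noiseless):
        trace, log = estim_noiseless
        filtered = bandpass_filter(trace)
        onsets = detect_stimulus_onsets(filtered)
        events = detect_aps(filtered, onsets=onsets)
        res = match_across_channels(
            [e for e in events if e.channel_id == "ch1"],
            [e for e in events if e.channel_id == "ch2"],
            models.geometry,
        )
        records, _ = assemble_responses(onsets, res.pairs)
        finalize_latencies(records, models.geometry)
        aps = sorted(
            (ap for r in records for ap in r.aps),
            key=lambda a: a.ch1_event.positive_peak_time,
        )
        truth = log.events.sort_values("anode1_arrival_s")
        assert len(aps) == len(truth)
        for ap, (_, row) in zip(aps, truth.iterrows()):
            assert ap.fiber_class == row.fiber


class TestSuccessRate:
    def _records(self, flags):
        out = []
        for i, flag in enumerate(flags):
            record = ResponseRecord(i, MSTIM, float(i))
            if flag:
                record.aps.append(_pap(10.0))
            out.append(record)
        return out

    def test_zero_and_one(self):
        assert success_rate(self._records([False] * 20)) == 0.0
        assert success_rate(self._records([True] * 20)) == 1.0

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            success_rate([])

    @given(st.lists(st.booleans(), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_order_and_duplication_invariance(self, flags):
        records = self._records(flags)
        rate = success_rate(records)
        assert success_rate(list(reversed(records))) == rate
        assert success_rate(records + records) == pytest.approx(rate)

    def test_binomial_consistency(self, rng):
        planted = 0.6
        n = 500
        records = self._records(rng.random(n) < planted)
        bound = 1.96 * np.sqrt(planted * (1 - planted) / n)
        assert abs(success_rate(records) - planted) < bound + 0.01
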