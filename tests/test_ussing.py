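"""Short-circuit-current segmentation, CFTR-activity summaries and QC."""

import numpy as np
import pytest

from theratype.synthetic import gen_ussing_trace
from theratype.ussing import (
    EventSchedule,
    IscTrace,
    ScheduleEvent,
    SegmentResponse,
    cftr_activity,
    fold_change,
    segment_trace,
    teer_qc,
)


def _flat_trace(level=5.0, t_end=800.0, rate=2.0):
    t = np.arange(0.0, t_end, 1.0 / rate)
    return IscTrace(times=t, isc=np.full_like(t, level))


def _schedule():
    return EventSchedule.default(start=120.0, spacing=120.0)


class TestSegmentation:
    def test_flat_trace_all_zero_deltas(self):
        responses = segment_trace(_flat_trace(), _schedule())
        assert len(responses) == 5
        assert all(r.delta_isc == pytest.approx(0.0) for r in responses)

    def test_noiseless_step_at_forskolin(self):
        trace = _flat_trace()
        sched = _schedule()
        fsk_time = sched.events[2].time
        trace.isc = trace.isc + 10.0 * (trace.times >= fsk_time)
        responses = segment_trace(trace, sched)
        by = {r.compound: r.delta_isc for r in responses}
        assert by["forskolin"] == pytest.approx(10.0)
        assert by["amiloride"] == pytest.approx(0.0)

    def test_sum_of_deltas_telescopes_on_noiseless_trace(self):
        deltas = {"amiloride": -2.0, "IVA": 1.0, "forskolin": 4.0,
                  "CFTRinh-172": -5.0, "ATP": 2.5}
        trace, sched, _ = gen_ussing_trace(
            seed=0, deltas=deltas, noise_sd=0.0, drift=0.0
        )
        responses = segment_trace(trace, sched)
        total = sum(r.delta_isc for r in responses)
        first_plateau = np.median(trace.isc[trace.times < sched.events[0].time])
        last_plateau = np.median(trace.isc[trace.times > trace.times[-1] - 30.0])
        assert total == pytest.approx(last_plateau - first_plateau, abs=0.05)

    def test_synthetic_recovery_within_tolerance(self):
        deltas = {"amiloride": -2.0, "IVA": 1.5, "forskolin": 4.5,
                  "CFTRinh-172": -6.0, "ATP": 2.0}
        trace, sched, truth = gen_ussing_trace(
            seed=5, deltas=deltas, noise_sd=0.05, drift=0.001
        )
        responses = segment_trace(trace, sched, correct_drift=True)
        for r in responses:
            assert r.delta_isc == pytest.approx(truth["deltas"][r.compound], abs=0.2)

    def test_event_outside_trace_rejected(self):
        sched = EventSchedule([ScheduleEvent(5000.0, "forskolin", "basal", 10.0)])
        with pytest.raises(ValueError, match="forskolin.*outside"):
            segment_trace(_flat_trace(), sched)

    def test_window_exceeding_gap_rejected(self):
        with pytest.raises(ValueError, match="plateau window"):
            segment_trace(_flat_trace(), _schedule(), plateau_window=200.0)


class TestCftrActivity:
    def test_dmso_condition_equals_its_forskolin_response(self):
        responses = [
            SegmentResponse("amiloride", 5.0, 3.0),
            SegmentResponse("DMSO", 3.0, 3.0),
            SegmentResponse("forskolin", 3.0, 6.45),
        ]
        s = cftr_activity(responses, "DMSO", baseline_fsk=3.45)
        assert s.total_current == pytest.approx(3.45)
        assert s.fold_change == pytest.approx(1.0)
        assert s.above_baseline == pytest.approx(0.0)

    def test_potentiator_adds_to_forskolin(self):
        responses = [
            SegmentResponse("IVA", 3.0, 3.0),
            SegmentResponse("forskolin", 3.0, 3.0 + 3.45),
        ]
        s = cftr_activity(responses, "IVA", baseline_fsk=3.45)
        assert s.fold_change == pytest.approx(1.0)
        assert s.above_baseline == pytest.approx(0.0)

    def test_identity_above_baseline_plus_baseline_is_total(self):
        responses = [
            SegmentResponse("IVA", 3.0, 4.0),
            SegmentResponse("forskolin", 4.0, 9.0),
        ]
        s = cftr_activity(responses, "ELX/TEZ+IVA", baseline_fsk=3.45)
        assert s.above_baseline + s.baseline_fsk == pytest.approx(s.total_current)

    def test_missing_forskolin_rejected(self):
        with pytest.raises(ValueError, match="forskolin"):
            cftr_activity([SegmentResponse("IVA", 0, 1)], "IVA", 3.45)

    def test_inhibitor_reverses_activated_current(self):
        deltas = {"IVA": 1.5, "forskolin": 4.5, "CFTRinh-172": -6.0}
        trace, sched, _ = gen_ussing_trace(seed=2, deltas=deltas, noise_sd=0.02)
        responses = segment_trace(trace, sched, correct_drift=True)
        s = cftr_activity(responses, "IVA", 3.45)
        assert s.inh172_response == pytest.approx(-s.total_current, abs=0.3)


class TestFoldChange:
    @pytest.mark.parametrize(
        "total,baseline,expected",
        [
            (3.45, 3.45, 1.00),
            (5.73, 3.45, 1.66),
            (27.19, 27.19 - 25.75, 18.88),
        ],
    )
    def test_printed_worked_examples(self, total, baseline, expected):
        assert round(fold_change(total, baseline), 2) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            fold_change(5.0, 0.0)


class TestTeerQc:
    @pytest.mark.parametrize(
        "teer,expected",
        [(242.3, True), (188.0, True), (1250.0, True), (100.0, False), (1300.0, False)],
    )
    def test_maturity_window(self, teer, expected):
        assert teer_qc(teer) is expected

    def test_nonpositive_teer_rejected(self):
        with pytest.raises(ValueError, match="TEER"):
            teer_qc(0.0)


def test_schedule_times_must_increase():
    with pytest.raises(ValueError, match="increasing"):
        EventSchedule(
            [
                ScheduleEvent(100.0, "amiloride"),
                ScheduleEvent(50.0, "forskolin", "basal"),
            ]
        )


def test_unknown_compound_rejected():
    with pytest.raises(ValueError, match="unknown compound"):
        ScheduleEvent(10.0, "caffeine")
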