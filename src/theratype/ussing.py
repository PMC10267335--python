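"""Short-circuit-current (Ussing chamber) trace analysis for CFTR theratyping.

A differentiated airway epithelium mounted in an Ussing chamber yields a
short-circuit current trace Isc(t) in µA/cm².  Compounds are added in a
fixed order — amiloride (ENaC block), an acute potentiator (ivacaftor, IVA)
or its DMSO vehicle, forskolin (cAMP activation of CFTR), CFTRinh-172
(CFTR-specific block, a QC for CFTR dependence), and ATP (calcium-activated
chloride currents).  Each addition drives the current to a new plateau; the
per-compound response ΔIsc is the difference between the plateau reached
after the addition and the plateau immediately before it.

Cumulative ΔIsc in response to forskolin plus the acute potentiator is the
total CFTR-activated current of a condition.  The forskolin response of the
vehicle (DMSO) condition is the baseline CFTR activity, ΔIsc-Fsk.  A
condition's fold change is total/baseline; its above-baseline increment is
total − baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IscTrace",
    "ScheduleEvent",
    "EventSchedule",
    "SegmentResponse",
    "CftrActivitySummary",
    "DEFAULT_SCHEDULE",
    "segment_trace",
    "cftr_activity",
    "fold_change",
    "teer_qc",
]

KNOWN_COMPOUNDS = {"amiloride", "DMSO", "IVA", "forskolin", "CFTRinh-172", "ATP"}

#: TEER window (Ω·cm²) regarded as a mature, junction-intact epithelium.
TEER_MATURE_RANGE = (188.0, 1250.0)


@dataclass
class IscTrace:
    """One short-circuit current recording with its culture metadata."""

    times: np.ndarray
    isc: np.ndarray
    genotype: str = ""
    treatment: str = ""
    teer: float | None = None
    culture_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.isc = np.asarray(self.isc, dtype=float)
        if self.times.shape != self.isc.shape or self.times.size < 2:
            raise ValueError("trace needs matching times/isc with ≥ 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")


@dataclass(frozen=True)
class ScheduleEvent:
    time: float
    compound: str
    compartment: str = "apical"
    concentration_um: float = 0.0

    def __post_init__(self) -> None:
        if self.compound not in KNOWN_COMPOUNDS:
            raise ValueError(
                f"unknown compound {self.compound!r}; expected one of "
                f"{sorted(KNOWN_COMPOUNDS)}"
            )
        if self.compartment not in ("apical", "basal"):
            raise ValueError(f"compartment must be apical/basal, got {self.compartment!r}")


@dataclass
class EventSchedule:
    """Ordered compound additions segmenting a recording."""

    events: list[ScheduleEvent]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    @classmethod
    def default(
        cls, start: float = 300.0, spacing: float = 300.0, potentiator: str = "IVA"
    ) -> "EventSchedule":
        """The standard addition sequence: apical amiloride 100 µM, apical
        potentiator (or DMSO vehicle) 10 µM, basal forskolin 10 µM, apical
        CFTRinh-172 30 µM, apical ATP 100 µM."""
        t = start
        events = []
        for compound, compartment, conc in (
            ("amiloride", "apical", 100.0),
            (potentiator, "apical", 10.0),
            ("forskolin", "basal", 10.0),
            ("CFTRinh-172", "apical", 30.0),
            ("ATP", "apical", 100.0),
        ):
            events.append(ScheduleEvent(t, compound, compartment, conc))
            t += spacing
        return cls(events)


DEFAULT_SCHEDULE = EventSchedule.default()


@dataclass
class SegmentResponse:
    compound: str
    pre_plateau: float
    post_plateau: float

    @property
    def delta_isc(self) -> float:
        return self.post_plateau - self.pre_plateau


@dataclass
class CftrActivitySummary:
    """Baseline, total and relative CFTR-activated current for one condition."""

    condition: str
    baseline_fsk: float
    total_current: float
    fold_change: float
    above_baseline: float
    inh172_response: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _median_window(trace: IscTrace, end_time: float, window: float) -> float:
    lo = end_time - window
    mask = (trace.times >= lo) & (trace.times < end_time)
    if not np.any(mask):
        raise ValueError(
            f"no samples in plateau window [{lo:.1f}, {end_time:.1f}) s"
        )
    return float(np.median(trace.isc[mask]))


def segment_trace(
    trace: IscTrace,
    schedule: EventSchedule,
    plateau_window: float = 30.0,
    correct_drift: bool = False,
) -> list[SegmentResponse]:
    """Per-compound ΔIsc via trailing-median plateaus.

    The plateau before an event is the median Isc over ``plateau_window``
    seconds immediately preceding it; the plateau attained after the event
    is read over the window immediately preceding the *next* event (or the
    trace end), by which time the response has settled.

    With ``correct_drift`` a linear baseline drift, estimated by
    least-squares over the pre-first-event stretch of the recording, is
    subtracted before plateaus are read.  Off by default: the acquisition
    protocol already stabilises the baseline before additions begin.
    """
    if plateau_window <= 0:
        raise ValueError("plateau_window must be positive")
    if correct_drift:
        pre = trace.times < schedule.events[0].time
        if np.count_nonzero(pre) < 2:
            raise ValueError("too few pre-event samples to estimate drift")
        slope = np.polyfit(trace.times[pre], trace.isc[pre], 1)[0]
        trace = IscTrace(
            times=trace.times,
            isc=trace.isc - slope * (trace.times - trace.times[0]),
            genotype=trace.genotype,
            treatment=trace.treatment,
            teer=trace.teer,
            culture_id=trace.culture_id,
        )
    t0, t1 = trace.times[0], trace.times[-1]
    bounds = [e.time for e in schedule.events] + [t1]
    for i, ev in enumerate(schedule.events):
        if not (t0 < ev.time <= t1):
            raise ValueError(
                f"event {ev.compound!r} at {ev.time} s lies outside the "
                f"trace span [{t0}, {t1}] s"
            )
        gap = bounds[i + 1] - ev.time
        if plateau_window > gap:
            raise ValueError(
                f"plateau window {plateau_window} s exceeds the {gap:.1f} s "
                f"gap after event {ev.compound!r}"
            )
    if schedule.events and schedule.events[0].time - t0 < plateau_window:
        raise ValueError(
            f"plateau window {plateau_window} s exceeds the pre-first-event span"
        )
    responses = []
    for i, ev in enumerate(schedule.events):
        pre = _median_window(trace, ev.time, plateau_window)
        post = _median_window(trace, bounds[i + 1], plateau_window)
        responses.append(SegmentResponse(ev.compound, pre, post))
    return responses


def _find(responses: list[SegmentResponse], compound: str) -> SegmentResponse | None:
    for r in responses:
        if r.compound == compound:
            return r
    return None


def cftr_activity(
    responses: list[SegmentResponse],
    condition: str,
    baseline_fsk: float,
) -> CftrActivitySummary:
    """Total CFTR-activated current and its relation to baseline.

    Total current is the cumulative ΔIsc of forskolin plus the acute
    potentiator (IVA) when one was added; in the vehicle (DMSO) condition
    the total is the forskolin response alone and defines ΔIsc-Fsk.
    """
    fsk = _find(responses, "forskolin")
    if fsk is None:
        raise ValueError("no forskolin response in segmented trace")
    total = fsk.delta_isc
    iva = _find(responses, "IVA")
    if iva is not None:
        total += iva.delta_isc
    inh = _find(responses, "CFTRinh-172")
    return CftrActivitySummary(
        condition=condition,
        baseline_fsk=baseline_fsk,
        total_current=total,
        fold_change=fold_change(total, baseline_fsk),
        above_baseline=total - baseline_fsk,
        inh172_response=None if inh is None else inh.delta_isc,
    )


def fold_change(total: float, baseline: float) -> float:
    """Ratio of a condition's total CFTR-activated current to baseline."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    return total / baseline


def teer_qc(
    teer: float,
    range_low: float = TEER_MATURE_RANGE[0],
    range_high: float = TEER_MATURE_RANGE[1],
) -> bool:
    """Whether a TEER reading (Ω·cm²) falls in the mature-epithelium window
    (inclusive at both ends)."""
    if teer <= 0:
        raise ValueError(f"TEER must be positive, got {teer}")
    return range_low <= teer <= range_high


def read_trace_csv(path, **metadata) -> IscTrace:
    """Read a trace CSV with columns time_s, isc_uA_per_cm2."""
    df = pd.read_csv(path)
    required = {"time_s", "isc_uA_per_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return IscTrace(
        times=df["time_s"].to_numpy(),
        isc=df["isc_uA_per_cm2"].to_numpy(),
        **metadata,
    )
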