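"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its analysis assumes —
two-state residue–ligand distance dynamics, triplicate CT values under a
two-allele mixture with partial degradation of one isoform, piecewise-
plateau current traces with drift and noise, oscillating pixel stacks, and
blot lanes with a loading-control channel — and returns both the synthetic
input and a machine-readable truth record for recovery testing.  A fixed
seed yields identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allele_quant import REFERENCE_TARGET
from .cbf import PixelStack
from .trajectory import ContactMetricSpec, DistanceSeries, SIGMA_METRIC
from .ussing import EventSchedule, IscTrace

__all__ = [
    "gen_distance_series",
    "gen_ct_table",
    "gen_ussing_trace",
    "gen_cbf_stack",
    "gen_blot_lanes",
]


def gen_distance_series(
    seed: int,
    occupancy: float,
    contact_mean: float = 6.6,
    contact_sd: float = 0.2,
    disrupted_mean: float = 10.7,
    disrupted_sd: float = 0.9,
    n_frames: int = 2000,
    switch_rate: float = 0.02,
    metric: ContactMetricSpec = SIGMA_METRIC,
    replicate_id: str = "rep1",
    frame_interval_ns: float = 1.0,
) -> tuple[DistanceSeries, dict]:
    """Two-state (contact/disrupted) Markov-switching distance series.

    The hidden state follows a two-state Markov chain whose stationary
    contact probability equals ``occupancy``; within each state, distances
    are Gaussian around the state mean (clipped at zero).  ``switch_rate``
    scales the per-frame transition probabilities without changing the
    stationary occupancy; smaller values give longer dwell times, mimicking
    the long bound/disrupted episodes seen in microsecond trajectories.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy must lie in [0, 1], got {occupancy}")
    if not 0.0 < switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    # state 1 = contact; transitions scaled so the chain's stationary
    # distribution is exactly (1-occupancy, occupancy)
    p_enter = switch_rate * occupancy        # disrupted -> contact
    p_leave = switch_rate * (1.0 - occupancy)  # contact -> disrupted
    states = np.empty(n_frames, dtype=bool)
    states[0] = rng.random() < occupancy
    u = rng.random(n_frames)
    for i in range(1, n_frames):
        if states[i - 1]:
            states[i] = u[i] >= p_leave
        else:
            states[i] = u[i] < p_enter
    means = np.where(states, contact_mean, disrupted_mean)
    sds = np.where(states, contact_sd, disrupted_sd)
    distances = np.clip(rng.normal(means, sds), 0.0, None)
    series = DistanceSeries(
        metric=metric,
        replicate_id=replicate_id,
        times=np.arange(n_frames, dtype=float) * frame_interval_ns,
        distances=distances,
    )
    truth = {
        "seed": seed,
        "occupancy": occupancy,
        "empirical_occupancy": float(states.mean()),
        "contact_mean": contact_mean,
        "contact_sd": contact_sd,
        "disrupted_mean": disrupted_mean,
        "disrupted_sd": disrupted_sd,
        "n_frames": n_frames,
    }
    return series, truth


def gen_ct_table(
    seed: int,
    allele_fractions: tuple[float, float] = (0.5, 0.5),
    degradation: float = 0.5094,
    ct_noise_sd: float = 0.1,
    reference_ct: float = 20.0,
    n_replicates: int = 3,
    n_calibrators: int = 3,
    sample_id: str = "patient",
) -> tuple[pd.DataFrame, dict]:
    """Triplicate CT table for a two-allele transcript mixture.

    The test sample transcribes the two alleles at ``allele_fractions``
    (summing to 1); ``degradation`` removes that fraction of allele A's
    transcript (the splicing-defective isoform lost to decay).  Calibrator
    samples carry both alleles intact at 50:50.  CT values follow
    ``CT = reference_ct − log2(quantity) + offset + noise`` with Gaussian
    cycle noise, mirroring ideal doubling per cycle.
    """
    f_a, f_b = allele_fractions
    if abs(f_a + f_b - 1.0) > 1e-9:
        raise ValueError("allele fractions must sum to 1")
    if not 0.0 <= degradation <= 1.0:
        raise ValueError("degradation must lie in [0, 1]")
    q_a = f_a * (1.0 - degradation)
    q_b = f_b
    if q_a + q_b == 0:
        raise ValueError("zero total transcript quantity")
    rng = np.random.default_rng(seed)
    offset = 5.0  # places allele CTs in a plausible high-20s range
    rows = []

    def emit(sid: str, target: str, quantity: float) -> None:
        if target == REFERENCE_TARGET:
            base = reference_ct
        else:
            if quantity <= 0:
                return  # non-detect: no rows for this target
            base = reference_ct + offset - np.log2(quantity)
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample_id": sid,
                    "target": target,
                    "replicate": rep + 1,
                    "ct": base + rng.normal(0.0, ct_noise_sd),
                }
            )

    for sid, qa, qb in [
        (sample_id, q_a, q_b),
        *[(f"calibrator{i+1}", 0.5, 0.5) for i in range(n_calibrators)],
    ]:
        emit(sid, "allele_a_primer", qa)
        emit(sid, "allele_b_primer", qb)
        emit(sid, REFERENCE_TARGET, 1.0)

    total = q_a + q_b
    truth = {
        "seed": seed,
        "degradation_pct": 100.0 * degradation,
        "pct_allele_a": 100.0 * q_a / total,
        "pct_allele_b": 100.0 * q_b / total,
        "calibrator_ids": [f"calibrator{i+1}" for i in range(n_calibrators)],
        "sample_id": sample_id,
    }
    return pd.DataFrame(rows), truth


def gen_ussing_trace(
    seed: int,
    deltas: dict[str, float] | None = None,
    baseline_level: float = 5.0,
    tau: float = 10.0,
    drift: float = 0.001,
    noise_sd: float = 0.05,
    sampling_rate: float = 2.0,
    schedule: EventSchedule | None = None,
    settle: float = 60.0,
    genotype: str = "",
    treatment: str = "",
) -> tuple[IscTrace, EventSchedule, dict]:
    """Piecewise-plateau short-circuit current trace.

    Each scheduled compound shifts the current by its configured ΔIsc
    through an exponential transition with time constant ``tau`` (s);
    linear ``drift`` (µA/cm²/s) and Gaussian ``noise_sd`` are superimposed.
    ``settle`` seconds of recording precede the first event and follow the
    last.
    """
    if schedule is None:
        schedule = EventSchedule.default(start=settle + 60.0, spacing=120.0)
    if deltas is None:
        deltas = {"amiloride": -2.0, "forskolin": 3.45, "CFTRinh-172": -3.45}
    event_times = [e.time for e in schedule.events]
    gaps = np.diff(event_times + [event_times[-1] + settle + 60.0])
    if tau >= gaps.min():
        raise ValueError(
            f"transition time constant {tau} s must be below the smallest "
            f"inter-event gap {gaps.min():.1f} s"
        )
    rng = np.random.default_rng(seed)
    t_end = event_times[-1] + settle + 60.0
    times = np.arange(0.0, t_end, 1.0 / sampling_rate)
    isc = np.full_like(times, baseline_level)
    true_deltas = {}
    for ev in schedule.events:
        d = float(deltas.get(ev.compound, 0.0))
        true_deltas[ev.compound] = d
        after = times >= ev.time
        isc[after] += d * (1.0 - np.exp(-(times[after] - ev.time) / tau))
    isc += drift * times + rng.normal(0.0, noise_sd, size=times.size)
    trace = IscTrace(
        times=times, isc=isc, genotype=genotype, treatment=treatment
    )
    truth = {
        "seed": seed,
        "deltas": true_deltas,
        "baseline_level": baseline_level,
        "tau": tau,
        "drift": drift,
        "noise_sd": noise_sd,
    }
    return trace, schedule, truth


def gen_cbf_stack(
    seed: int,
    frequency: float = 5.43,
    amplitude: float = 10.0,
    noise_sd: float = 0.0,
    frame_rate: float = 100.0,
    duration: float = 5.0,
    shape: tuple[int, int] = (16, 16),
    background_fraction: float = 0.2,
    baseline: float = 100.0,
    field_id: str = "field1",
    culture_id: str = "culture1",
) -> tuple[PixelStack, dict]:
    """Sinusoidally oscillating pixel stack with random per-pixel phase.

    A ``background_fraction`` of pixels stay static (non-ciliated surface);
    the rest oscillate at ``frequency`` Hz with independent phases, plus
    additive Gaussian noise.
    """
    if frequency >= frame_rate / 2.0 and amplitude > 0:
        raise ValueError(
            f"frequency {frequency} Hz violates the Nyquist limit "
            f"{frame_rate / 2.0} Hz"
        )
    rng = np.random.default_rng(seed)
    n_t = int(round(duration * frame_rate))
    h, w = shape
    n_px = h * w
    t = np.arange(n_t) / frame_rate
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_px)
    static = rng.random(n_px) < background_fraction
    amp = np.where(static, 0.0, amplitude)
    frames = baseline + amp[None, :] * np.sin(
        2.0 * np.pi * frequency * t[:, None] + phases[None, :]
    )
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    stack = PixelStack(
        frames=frames.reshape(n_t, h, w),
        frame_rate=frame_rate,
        field_id=field_id,
        culture_id=culture_id,
    )
    truth = {
        "seed": seed,
        "frequency": frequency,
        "amplitude": amplitude,
        "noise_sd": noise_sd,
        "frame_rate": frame_rate,
        "n_frames": n_t,
    }
    return stack, truth


def gen_blot_lanes(
    seed: int,
    levels: dict[str, float] | None = None,
    loads_ug: dict[str, float] | None = None,
    exposures: dict[str, float] | None = None,
    control_noise: float = 0.0,
    base_intensity: float = 1000.0,
) -> tuple[pd.DataFrame, dict]:
    """Blot lanes with unequal loading and a proportional loading control.

    Band C intensity = (level/100) × loaded µg × exposure × base; the
    loading-control intensity scales with loaded µg and exposure, times a
    multiplicative noise factor of SD ``control_noise``.  Because both
    channels share the lane's load and exposure, the percent-of-WT readout
    cancels them exactly in the noiseless case.
    """
    if levels is None:
        levels = {"WT": 100.0, "patient": 3.18}
    if loads_ug is None:
        loads_ug = {c: (20.0 if c == "WT" else 40.0) for c in levels}
    if exposures is None:
        exposures = {c: 1.0 for c in levels}
    rng = np.random.default_rng(seed)
    rows = []
    for condition, level in levels.items():
        if level < 0:
            raise ValueError(f"level for {condition!r} must be ≥ 0")
        load = loads_ug[condition]
        exposure = exposures[condition]
        factor = 1.0 + (rng.normal(0.0, control_noise) if control_noise > 0 else 0.0)
        rows.append(
            {
                "lane_id": condition,
                "condition": condition,
                "band_c_intensity": (level / 100.0) * load * exposure * base_intensity,
                "calnexin_intensity": load * exposure * base_intensity * factor,
                "protein_ug": load,
            }
        )
    truth = {"seed": seed, "levels": dict(levels), "control_noise": control_noise}
    return pd.DataFrame(rows), truth
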