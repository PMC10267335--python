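"""Short-circuit-current segmentation and CFTR-activity summary.

Simulates a drifting, noisy Ussing-chamber recording with the standard
compound sequence (amiloride, IVA, forskolin, CFTRinh-172, ATP), recovers
each compound's ΔIsc, and expresses the potentiated response relative to a
vehicle baseline.
"""

from theratype import synthetic, ussing

truth_deltas = {"amiloride": -2.0, "IVA": 1.5, "forskolin": 4.5,
                "CFTRinh-172": -6.0, "ATP": 2.0}
trace, schedule, truth = synthetic.gen_ussing_trace(
    seed=11, deltas=truth_deltas, noise_sd=0.1, drift=0.001
)
responses = ussing.segment_trace(trace, schedule, correct_drift=True)
for r in responses:
    print(f"{r.compound:>12}: ΔIsc {r.delta_isc:+6.2f} µA/cm² "
          f"(truth {truth['deltas'][r.compound]:+.2f})")

baseline = 3.45  # ΔIsc-Fsk of the vehicle (DMSO) condition
summary = ussing.cftr_activity(responses, "IVA", baseline)
print()
print(f"total CFTR-activated current: {summary.total_current:.2f} µA/cm² "
      f"(forskolin + acute potentiator)")
print(f"fold change vs baseline {baseline}: {summary.fold_change:.2f}")
print(f"above baseline: {summary.above_baseline:+.2f} µA/cm²")
print(f"CFTRinh-172 QC response: {summary.inh172_response:+.2f} µA/cm² "
      "(should roughly reverse the activated current)")
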