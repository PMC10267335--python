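"""Contact occupancy of the NBD2 residue 1291 — Mg2+ interaction.

Generates three replicate synthetic distance series mimicking a mutant in
which the metal-coordination contact is intact for ~57% of simulation time,
then summarises occupancy and pooled distance statistics.
"""

from theratype import synthetic, trajectory

series = [
    synthetic.gen_distance_series(seed=s, occupancy=0.57, n_frames=2000,
                                  replicate_id=f"rep{s + 1}")[0]
    for s in range(3)
]
summary = trajectory.summarize_distances(series)

print(f"metric {summary.metric} (contact below {summary.threshold:g} Å)")
print(f"per-replicate occupancy: "
      + ", ".join(f"{f:.1%}" for f in summary.per_replicate_fraction))
print(f"pooled occupancy: {summary.pooled_fraction:.1%} "
      f"of {summary.n_frames_total} frames")
print(f"pooled distance: {summary.mean_distance:.1f} ± {summary.sd_distance:.1f} Å")
print()
print("The pooled occupancy is the fraction of all simulation data in which")
print("the residue–ion contact is intact; partial occupancy indicates an")
print("unstable ATP/Mg2+ binding mode, i.e. a gating-defect signature.")
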