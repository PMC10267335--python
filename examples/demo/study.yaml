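# Demo theratyping study: published summary measurements as worked-example
# inputs plus seeded synthetic raw data for every stage.
seed: 42
stages:
  trajectory:
    occupancy: 0.57      # fraction of frames with the 1291-Mg2+ contact intact
    n_frames: 2000
    replicates: 3
  qpcr:
    degradation: 0.5094  # fraction of the splicing-defective allele degraded
    ct_noise_sd: 0.1
  ussing:
    worked_examples_csv: isc_worked_examples.csv
    synthetic:
      noise_sd: 0.05
  cbf:
    frequency: 5.43      # Hz
    n_fields: 3
    noise_sd: 1.0
  blot:
    wt_lane: WT
    levels:              # band C as percent of the wild-type lane
      WT: 100.0
      F508del/F508del: 2.1
      F508del/F508del+ETI: 29.36
      Q1291H/F508del: 3.18
      Q1291H/F508del+IVA: 5.06
      Q1291H/F508del+ELX/TEZ: 11.92
      Q1291H/F508del+ETI: 9.90
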