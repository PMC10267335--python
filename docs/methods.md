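# Methods

This note documents the models behind each analysis stage, the parameters
that matter, what the synthetic generators emulate (and deliberately do
not), and the numerical choices made where the design was open.

## Trajectory contact statistics

A binding-site contact is summarised by a scalar distance between one atom
of the protein and one atom of the ligand complex. The two built-in
metrics target the NBD ATP/Mg²⁺ site of CFTR:

- **λ** — backbone amide nitrogen of residue 551 to the ATP γ-phosphate
  phosphorus, contact threshold 5 Å. The backbone N is used because
  glycine 551 has no side-chain amide, so it is the only unambiguous
  single-atom reading; the γ-phosphate is represented by its phosphorus.
- **Σ** — alpha carbon of residue 1291 to the Mg²⁺ ion, threshold 7 Å.
  The Cα is used even though the contact is physically made by the side
  chain: a Cα distance is insensitive to rotamer flips and needs no
  per-mutant atom naming. Users who want a side-chain reading can supply
  their own `AtomSelector`.

A frame is in contact when the distance is **strictly below** the
threshold; a tie at exactly the threshold counts as not-in-contact.
Occupancy is pooled **frame-weighted** over replicates (total frames below
/ total frames), which is the "fraction of all simulation data" reading;
the mean of per-replicate fractions differs when replicate lengths differ
and is reported alongside, not used. Distance mean ± SD is computed over
pooled frames with the sample (n−1) SD; per-replicate means are also
emitted since either convention appears in the literature and the choice
is not derivable from a printed "mean ± SD" alone.

Statistics are frame-based, not time-weighted; when no frame times are
given they default to 0, 1, 2, … ns. Input is multi-model PDB (parsed by
biotite) or plain tabular CSV; binary trajectory formats are an adapter
concern outside the core, which keeps the statistics testable without an
MD stack. Running simulations is out of scope: the package analyses
distance series, it does not produce them.

### Two-state generator and the occupancy bound

`gen_distance_series` draws a hidden two-state (contact/disrupted) Markov
chain whose stationary contact probability is the configured occupancy;
within each state, distances are Gaussian about the state mean.
`switch_rate` scales the transition probabilities without changing the
stationary law: small values give the long dwell episodes seen in
microsecond trajectories (disruption events lasting hundreds of ns),
`switch_rate=1` gives per-frame-independent states.

The recovery tests assert |estimated − configured occupancy| ≤
3·√(p(1−p)/n). That binomial bound is only valid in the iid regime with
state distance distributions well separated from the threshold: dwell-time
clustering inflates the variance of the occupancy estimate roughly by the
dwell length, and a contact-state Gaussian whose mean sits within ~2 SD of
the threshold (e.g. 6.6 ± 0.2 Å against 7 Å) leaks ~2% of its mass across
it, biasing the count. Recovery tests therefore run the generator with
`switch_rate=1` and a contact mean of 4.0 Å; the dwell-structured defaults
remain for narrative and demo use, where they better resemble real
trajectories. Passing recovery shows the estimator counts correctly — it
says nothing about force-field realism, which the generator does not
attempt.

## Allele-specific quantification

Technical replicates are aggregated by the arithmetic mean of CT, with no
outlier rejection; a non-detect replicate is dropped from the mean and a
fully non-detect target is an error rather than a CT = 40 imputation. The
amplification efficiency is fixed at 2 (the 2^(−ΔΔCT) doubling assumption)
and is configurable per call for primer sets with measured efficiencies.
Calibrator samples are named explicitly, never inferred from the table.

The degradation estimate assumes both alleles are transcribed 50:50, so
the intact allele's observed share is the expected yield of the defective
one. A negative estimate (defective allele above the intact one) signals
that this assumption fails for the sample; it is returned as-is with a
warning flag, not clamped, so violated assumptions stay visible.

The CT generator writes `CT = reference_CT − log₂(quantity) + offset +
ε`, ε ~ N(0, σ) per replicate, with calibrators at intact 50:50 — the
structure the comparative-CT method assumes exactly. With the default
cycle noise σ = 0.1 the per-seed allele-percentage error has SD ≈ 1.5
points, so recovery is asserted on the average over 100 seeded runs (mean
absolute error < 2 points for percentages, < 3 for degradation); a
per-seed 2-point guarantee would require either lower noise or more
replicates. What passing shows: the formula layer is unbiased and
correctly propagates the calibrator normalisation. What it does not show:
primer specificity, efficiency differences between allele primers, or NMD
kinetics — none of which the generator models.

## Short-circuit-current analysis

Plateaus are estimated as the **median** over a trailing window (default
30 s) immediately before each event; the response plateau is read over the
window immediately before the *next* event (or trace end), by which time
an exponential transition with τ ≈ 10 s has settled. The median is robust
to the occasional spike; the transition shape itself is not modelled.

The total CFTR-activated current of a condition is the cumulative ΔIsc of
forskolin plus the acute potentiator, added regardless of the
potentiator's sign (the additive reading of "cumulative"); the vehicle
condition's total is its forskolin response alone and defines the baseline
ΔIsc-Fsk. Identities `above_baseline = total − baseline` and
`fold = total/baseline` hold exactly; folds and increments are rounded to
two decimals only at the reporting surface. Isc is taken positive for
lumen-negative anion secretion and never sign-flipped; amiloride responses
are expected negative. The CFTRinh-172 response is carried as a QC: on a
CFTR-dependent trace it approximately reverses the activated current.

Baseline drift is not corrected by default — acquisition protocols
stabilise the baseline before additions — but `correct_drift=True`
subtracts a linear drift fitted by least squares to the pre-first-event
stretch. With the generator's drift of 0.001 µA/cm²/s and 2-minute event
spacing, uncorrected plateau differences carry a systematic ~0.12 µA/cm²
offset; the correction removes it, and recovery tests on drifting traces
use it. TEER maturity QC is inclusive at both ends of the 188–1250 Ω·cm²
window.

The trace generator superimposes exponential step responses, linear drift
and white Gaussian noise. It does not emulate spontaneous transients,
chamber-temperature artefacts, or slow rundown, so recovery results bound
estimator error only under well-behaved recordings.

## Ciliary beat frequency

Per-pixel series are mean-detrended, Hann-windowed, and zero-padded to the
next power of two before the real FFT; the field spectrum is the mean
per-pixel power spectrum, and the beat frequency is the argmax within the
search band. Averaging **power after** the transform makes the estimate
invariant to per-pixel phase, so spatially incoherent cilia do not cancel;
averaging pixels first would. Pixels with temporal variance below 10⁻¹² of
the maximum are excluded as static background. An all-constant stack is a
"no oscillation" error, not a 0 Hz answer.

The default search band is 0.5–30 Hz — wider than the physiological
3.0–11.1 Hz window, which is a QC flag rather than a hard filter, so an
abnormal beat is reported instead of silently forced in range. The band
must sit below Nyquist; at low frame rates callers narrow it (the test
sweep uses 0.5–12 Hz against frame rates down to 30 Hz). The spectral bin
width (frame rate / padded length) is reported with every estimate, and
noiseless recovery is within one bin across frame rates and durations.

The generator produces a fixed-frequency sinusoid with uniform random
per-pixel phase, optional white noise and a static-background pixel
fraction. Real recordings have spatially varying frequency, harmonics and
camera noise correlations the generator omits.

## Densitometry

The sole correction is division by the loading-control intensity; loaded
µg is metadata. Dividing by µg as well would double-correct, because the
loading control already scales with load — that proportionality is what
justifies loading unequal protein amounts to avoid signal saturation, and
the generator enforces it so the cancellation is exact on noiseless lanes.
Per-blot normalisation precedes any averaging across blots. Band
quantification itself (lane finding, background subtraction) is upstream
and out of scope; the module consumes integrated densities.

## Aggregation and reporting

Summary statistics are mean ± SEM (sample SD/√n), aggregated
replicate-culture → participant → genotype; at n = 1 the SEM is reported
as unavailable rather than 0. Inferential testing is deliberately left to
standard statistical software and reported descriptively. The pipeline
report isolates the run timestamp to a single line of `report.json`;
everything else is byte-deterministic given the config and seeds, which is
asserted by running the packaged demo study twice.

Problem sizes in the shipped tests and demo — 2 000–10 000 frames per
trajectory replicate, triplicate CT tables, ~13-minute traces sampled at
2 Hz, 5-s 8×8–16×16 pixel stacks, 50–100 seeded repeats — were chosen so
the estimators' error is dominated by the configured noise, not by sample
scarcity, while the full suite runs in seconds.

## Known limitations

- Occupancy statistics assume the distance series fully represents the
  contact; no angular (hydrogen-bond geometry) criteria are applied.
- The degradation estimate inherits the 50:50 transcription assumption
  and cannot separate missplicing from other decay routes.
- Plateau segmentation assumes responses settle within the inter-event
  gap; strongly overlapping responses would bias ΔIsc attribution.
- The CBF estimator reports a single dominant frequency per field;
  multimodal beating surfaces only as secondary peaks in the returned
  spectrum.
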