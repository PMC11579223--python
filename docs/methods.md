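# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `scrscore`. It is written for a maintainer or a reviewer
who wants to know *why* the pipeline behaves as it does, not just what
the API is.

## Scoring model

An event-related SCR is quantified trough-to-peak: the amplitude is the
rise from a local minimum (the response onset) to the subsequent local
maximum, and a response exists only if that rise is at least the
detection threshold *X* (default 0.02 μS). This demands a genuine
response shape — in contrast to baseline-corrected scoring, which
subtracts pre-event level from the in-window maximum and can score tonic
drift, or deconvolution methods, which estimate underlying sudomotor
activity rather than the observable response.

Responses are assigned to latency windows by **onset**: FIR [1, 4) s and
SIR [4, 7) s after CS onset, TIR [1, 4) s after CS offset. Windows are
half-open, so an onset exactly at 4.0 s belongs to SIR; window triples
are fully configurable for other CS durations (TIR is anchored at CS
offset so users never hand-compute sums).

### Extremum detection

`find_extrema` is a single left-to-right scan with a running extremum
(a delta-prominence walker). A peak is confirmed once the trace drops at
least *X* below the running maximum before exceeding it; a trough once
the trace rises at least *X* above the running minimum; confirmed
extrema alternate. Decisions with rationale:

- **Undetermined start.** The scan begins with no polarity, so a segment
  that opens mid-rise emits its first sample as a trough. Such records
  are logged at debug level: a response already underway at the window
  edge is exactly the kind of case a human should review.
- **Tie-breaking on plateaus.** A tied maximum takes the earliest sample
  (first time the peak value is reached); a tied minimum takes the
  latest (the sample where the rise leaves the minimum, i.e. the onset).
  The asymmetry matters only on exactly-flat data — real filtered traces
  never tie — but it makes the onset-based window rule behave sensibly
  on clean synthetic segments.
- **Trailing extrema are discarded.** An extremum is only ever emitted
  after the trace has moved *X* away from it; a rise still in progress at
  the end of a segment is not a confirmed peak.

### Pair selection

Within a window, all validated (trough, later peak) pairs with amplitude
≥ *X* and the trough in-window compete; the maximal-amplitude pair wins
(ties to the earliest pair). Selecting the matched pair rather than
independently taking the deepest trough and highest peak avoids
non-causal pairs (peak before trough). The peak may fall up to
`peak_horizon_s` (default 4 s) past the window end — responses that
begin in-window but complete after it are real responses, the main
behavioural difference from bracket-cutoff scoring tools — but never
past the segment, which is clipped at the next event onset. The unit
tests hold this selection to exact equality with an exhaustive
brute-force pair search over flank-validated samples.

When no pair qualifies the record is a non-response with amplitude 0 and
status `zero`; the status field preserves the hint that the value was
defaulted rather than measured. A window extending past truncated data
(e.g. the last trial's TIR when the recording stops early) is
`missing_artifact`, which the statistics treat as missing, never as 0.

## Preprocessing

Order: high-pass at the native rate → segment (L = 14 s per event) →
bin-mean resample to 50 Hz. L = 14 s covers the TIR end (CS 6 s + 4 s)
plus the 4 s peak horizon; with ITIs of at least 10 s, successive
segments never overlap at the default design.

**Filter realization.** A linear-phase windowed-sinc FIR (Hamming
window), −6 dB point at the 0.5 Hz cutoff, applied centred after
reflect-padding by one filter length: zero net delay, so trough/peak
latencies are unbiased, with start-of-record transients absorbed by the
padding. The tap count defaults to ~4 s of filter (4001 taps at
1000 Hz, scaled with the rate). Shorter kernels were rejected after
measuring their response: a 251-tap kernel at 1000 Hz leaves 0.05 Hz
drift at gain 0.87, i.e. it barely filters at all below its enormous
transition band; the 4001-tap default measures gain 0.0024 at 0.05 Hz
and 0.9996 at 2 Hz. The taps are mean-adjusted to an exactly zero sum so
a constant input maps to 0 at float precision (the raw Hamming stopband
would leave ~0.2% of the DC level).

**What the 0.5 Hz cutoff does to SCRs.** An SCR rises over ~1–2 s and
decays over several seconds; much of its energy lies *below* 0.5 Hz. Any
filter sharp enough to suppress 0.05 Hz drift while passing 2 Hz
therefore attenuates the SCR waveform itself: the unit biexponential
kernel comes through the default filter with a trough-to-peak of ~0.30.
This is a property of the prescribed cutoff, not of the implementation
(a gentler cutoff, e.g. 0.05 Hz, is one config flag away). Consequences
for validation are handled via the simulator's two-level ground truth
(below). Relative amplitudes, and hence agreement statistics, are
unaffected because the filter is linear and time-invariant.

**Resampling** is by contiguous time-bin means on the time axis (output
sample k averages input samples with timestamps in
[k/f_t, (k+1)/f_t)), so non-integer rate ratios work, integer ratios
reduce to exact block means, and equal rates are the identity. No
interpolation and no decimation: bin means at 50 Hz barely touch
SCR-band content while suppressing broadband noise.

## Synthetic sessions

`simulate_session` emulates a differential fear-conditioning session:
habituation/acquisition/extinction with 4/8/24 trials of each CS
(randomised order within phase), CS duration 6 s, ITIs uniform in
10–14 s, 1000 Hz, with a 15 s lead-in and tail. The trace is
baseline (5 μS) + slow sinusoidal drift (0.3 μS, 120 s period) + a sum
of SCR kernels + Gaussian noise (sd 0.005 μS) + Poisson step artifacts
(0.3/min, ±0.3 μS) — all seed-determined, all configurable, and all
switchable off via `SimDesign.noise_free()`.

The SCR kernel is a peak-normalised biexponential (difference of
exponentials, rise 0.75 s, decay 3 s; onset→peak latency ln(τd/τr)·τrτd/
(τd−τr) ≈ 1.39 s). Response amplitudes default to CS+ {FIR 0.5, SIR
0.35, TIR 0.8} μS and CS− {0.4, 0.25, 0.35} μS — mid-range values for
palmar recordings — with exponential habituation (rate 0.03 per
presentation of that CS) and lognormal trial-level variability (σ =
0.25). Onsets jitter uniformly within each latency window keeping
≥ 0.4 s from window boundaries, so the programmed interval of every
response is unambiguous. Every programmed interval responds by default
(`response_prob = 1`); non-responders, misses and artifacts are
exercised through explicit parameters rather than the default design.

**Two-level ground truth.** Each trial × interval row records the
*injected* kernel amplitude and the *realized* amplitude — the
trough-to-peak measurable on the clean phasic composite after the same
high-pass + resampling the scorer sees, extracted with
`scipy.signal.find_peaks` (an extremum detector independent of the
package's own walker) under the same window/horizon/threshold rules.
Realized amplitudes are the right yardstick for end-to-end recovery:
they account for the filter's attenuation of sub-0.5 Hz SCR energy and
for superposition of neighbouring responses. Recovery of *injected*
amplitudes (0.05–1.0 μS within 5%) is asserted with the high-pass
disabled, isolating detection fidelity from filter attenuation. A late,
heavily habituated CS− response whose realized rise falls below 0.02 μS
is recorded as realized amplitude 0 — the scorer is then required to
agree it is a non-response.

`simulate_rater` turns realized truth into one rater's scores: additive
Gaussian measurement noise on every target (negative results clip to
non-response, since a negative rise is not scoreable), plus an optional
outright miss rate. For two raters with noise σn over targets of
variance σt², the expected one-way agreement ICC is σt²/(σt² + σn²); the
tests require the empirical ICC over ≥ 500 targets to land within ±0.03
of that. Clipping at zero makes the additive-noise model slightly
mis-specified for near-zero targets, which contributes a small upward
bias well inside that band at the default σn = 0.03 μS.

**What the simulator does not emulate:** electrode drift nonlinearity,
respiration-coupled artifacts, overlapping responses from short-ITI
designs, non-stationary noise, or any physiologically calibrated
sudomotor model. Passing tests show the pipeline recovers what this
generative model produces; they do not certify scoring quality on real
data, which is why the workflow keeps a human-review stage.

## Agreement statistics

`icc_oneway` implements the one-way random-effects **agreement** ICC:
targets are random rows, rater identity is absorbed into error, so both
random and systematic rater differences lower the coefficient (a
constant per-rater offset reduces it; a constant added to all cells does
not). F = MS_B/MS_W on (n−1, n(k−1)) df with its p-value. Degenerate
all-identical matrices are defined as ICC = 1 with a warning; negative
ICCs are legitimate outputs. Missing/artifact targets are dropped
pairwise-complete with a logged count; non-responses enter as 0. Sample
SD uses n−1 throughout.

Score matrices come in two groupings, because "trial-by-trial vs
average" is underdetermined without a participant map: `trial_matrix`
pairs raters on (event, interval) targets within a session;
`average_matrix` first averages each rater's amplitudes per
(group, interval) using a caller-supplied event→group map (participant,
phase, condition…). The CLI report states which grouping produced it.

`bland_altman` reports the mean difference, SD of differences, and
agreement limits mean ± 1.96·SD; pairs outside the limits are the
discrepant scores, each carried with its pair mean for follow-up. The
CI of the mean difference is also reported but deliberately not used
for outlier flagging — flagging needs a dispersion band, not a
standard-error band. `pareto` tabulates human-assigned discrepancy
causes (counts descending, ties alphabetical, cumulative percentages);
assigning causes is qualitative work the tool does not automate.

## Numerical and I/O details

- Times are seconds from recording start; sample indexing is 0-based
  internally and never appears in files. At 50 Hz a sample's timestamp
  is its bin's left edge, so "trough at 4.00 s" is exact.
- The annotation CSV is UTF-8/LF with a fixed column order; times carry
  4 decimals (0.1 ms), values 6. Write→read round-trips to ≤ 0.5 ms and
  ≤ 1e-5 μS. Duplicate (event, interval, rater) keys are rejected on
  write; invariant violations are rejected on read with row numbers.
- MAT input covers both dialects (classic v5 via scipy.io, HDF5-based
  v7.3 via h5py) with user-named variables — no vendor struct layout is
  assumed, and a plain columnar text format exists so nothing binary is
  ever required. Marker channels convert to events at rising edges
  (threshold defaulting to half the channel maximum); an event at
  sample 0 is emitted and left to the user. The simulator writes all
  three formats, so the readers are tested against files the package
  generated itself.
- Scoring is deterministic: identical inputs and configuration yield
  byte-identical annotation CSVs.
- Problem sizes in the test suite and acceptance script (200 random
  segments for the oracle check, the full 72-trial design for recovery,
  three sessions ≈ 650 targets for the ICC band, 1000 pairs for
  Bland–Altman coverage) were chosen to make each statistic stable at
  the stated tolerance while keeping the whole suite fast.

## Known limitations

- The 0.5 Hz default cutoff attenuates SCR amplitude ~3× (see above);
  absolute amplitudes are comparable within a fixed configuration only.
- The walker anchors flanks at the segment start, so a response already
  rising at segment start is scored from its first sample; whether that
  is desired is study-specific (it is logged).
- No artifact rejection beyond the manual `missing_artifact` flag:
  respiration-driven artifact judgment is explicitly human work.
- Entire-interval (EIR) scoring, baseline-corrected scoring and
  model-based (deconvolution) estimation are out of scope.
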