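# scrscore

Semi-automated trough-to-peak scoring of event-related **skin conductance
responses (SCRs)** in the three classical latency windows of
fear-conditioning research — the first, second, and third interval
responses (FIR/SIR/TIR) — with the rater-agreement statistics used to
validate such scoring (one-way agreement ICC, Bland–Altman limits of
agreement, Pareto discrepancy tabulation) and a synthetic session
simulator that makes the whole pipeline testable without any recordings.

## Who this is for

Psychophysiology labs that score event-related electrodermal activity
trough-to-peak rather than by baseline correction or deconvolution:
scoring that requires a genuine response shape (a local minimum followed
by a validated rise) and assigns each response to a latency window by its
onset. The package is a headless library plus a small CLI; the intended
workflow is automatic scoring followed by human review of the annotation
CSV, with programmatic overrides replacing interactive marker dragging.

## The method

A recording (skin conductance in μS plus an event-marker channel,
typically 1000 Hz) is processed as:

1. **High-pass filter** — linear-phase windowed-sinc FIR, Hamming window,
   −6 dB cutoff 0.5 Hz, applied with zero net delay. This removes the
   tonic skin-conductance level and slow drift.
2. **Segmentation** — a window of L = 14 s after each stimulus (CS)
   onset.
3. **Resampling** — bin means down to 50 Hz.
4. **Trough-to-peak detection** — a single left-to-right scan tracking
   the running extremum: a peak is confirmed only when the trace has
   fallen at least the threshold *X* (default 0.02 μS) below it, a trough
   only when the trace has risen at least *X* above it. Among validated
   (trough, later peak) pairs whose **trough** lies in the half-open
   window — FIR [1, 4) s and SIR [4, 7) s after CS onset, TIR [1, 4) s
   after CS offset — the maximal-amplitude pair is retained. The peak may
   complete up to 4 s after the window closes. Windows with no qualifying
   pair are non-responses, scored 0; windows falling off truncated data
   are marked `missing_artifact` and treated as missing, not zero.
5. **Agreement statistics** — for two score sets (two raters, or program
   vs manual), the one-way random-effects agreement ICC

   ICC(1) = (MS_B − MS_W) / (MS_B + (k−1)·MS_W),  F = MS_B / MS_W,

   per trial or per participant average; Bland–Altman mean difference
   with limits mean ± 1.96·SD; and a Pareto table of discrepancy causes.

## Worked example

```sh
$ printf 'phases: [habituation, acquisition]\nseed: 7\n' > design.yaml
$ scrscore --log-level WARNING simulate --design design.yaml --out session.mat --truth truth.csv
wrote 24 events, 447.0 s -> session.mat
$ scrscore --log-level WARNING score --input session.mat --rater LJN --out scores.csv
scored 24 events -> 72 records (72 responses) -> scores.csv
$ head -4 scores.csv
event_index,interval,trough_time_s,trough_value_uS,peak_time_s,peak_value_uS,amplitude_uS,status,rater
1,FIR,16.8600,-0.105773,17.4600,0.045541,0.151314,auto,LJN
1,SIR,20.7000,-0.064744,23.3800,0.073126,0.137870,auto,LJN
1,TIR,22.8800,-0.172128,23.3800,0.073126,0.245254,auto,LJN
```

A simulated habituation + acquisition session (4 + 8 trials per CS, 24
events) is scored into 72 trial × interval records. Event 1's FIR is a
0.151 μS rise whose trough sits 1.86 s after the CS onset at 15 s; values
are negative-going because the high-pass has removed the ~5 μS tonic
level. Rescoring with a stricter threshold and comparing yields the
agreement report:

```sh
$ scrscore --log-level WARNING score --input session.mat --threshold 0.03 --rater RA --out scores_b.csv
scored 24 events -> 72 records (63 responses) -> scores_b.csv
$ scrscore --log-level WARNING agree --a scores.csv --b scores_b.csv --mode trial --report report.json
ICC=0.8947 F=18.00 n=72 -> report.json
```

The trial-by-trial agreement ICC of 0.895 (F(71, 72) = 18.0) quantifies
how much the stricter threshold changed the scores; `report.json` also
carries the Bland–Altman mean difference (0.0098 μS), the agreement
limits, and the outlying targets to feed into a Pareto analysis
(`scrscore pareto`).

Everything is equally usable as a library — `simulate_session`,
`score_session`, `apply_overrides`, `icc_oneway`, `bland_altman`,
`pareto` — see the docstrings and `docs/methods.md`.

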