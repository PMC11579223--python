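"""Synthetic differential fear-conditioning SC sessions with ground truth.

The generator emulates the standard paradigm: a CS+ and a CS− presented
over habituation / acquisition / extinction (4 / 8 / 24 trials of each CS
by default), CS duration 6 s, inter-trial intervals (CS offset to next
onset) jittered uniformly in 10–14 s, recorded at 1000 Hz. Each trial may
carry an event-related SCR in each latency window (FIR/SIR/TIR), built
from a peak-normalised biexponential (Bateman-style) kernel riding on a
tonic level, slow sinusoidal drift, Gaussian noise, and occasional step
artifacts. Everything is driven by a single seed.

Ground truth is emitted per trial × interval at two levels:

- ``injected_uS``: the programmed kernel amplitude;
- ``amplitude_uS`` (realized): the trough-to-peak measurable on the
  clean phasic composite after the same preprocessing the scorer uses.
  The 0.5 Hz high-pass that removes tonic drift also attenuates the SCR
  waveform itself (sub-0.5 Hz energy), so realized amplitudes are the
  right yardstick for end-to-end recovery. They are extracted with
  scipy.signal.find_peaks, an extremum detector independent of the
  package's own scoring walker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError
from .io import EventMarker, RecordingSession, ScoreRecord
from .preprocess import PreprocConfig, highpass, resample_mean
from .scoring import IntervalConfig

log = logging.getLogger(__name__)

PHASES = ("habituation", "acquisition", "extinction")


@dataclass
class SimDesign:
    """Design parameters of a simulated session.

    Trial counts, CS duration, and ITI jitter follow the differential
    conditioning paradigm (4/8/24 trials per CS; 6 s CS; 10–14 s ITI).
    Amplitudes (μS) and their dynamics are the generator's own realistic
    choices: CS+ responses exceed CS− outside habituation, amplitudes
    habituate exponentially over repetitions, and each response's onset
    jitters uniformly within its latency window, ≥ 0.4 s from the window
    boundaries so the programmed interval is unambiguous.
    """

    phases: tuple[str, ...] = PHASES
    trials_per_cs: dict = field(
        default_factory=lambda: {"habituation": 4, "acquisition": 8, "extinction": 24}
    )
    cs_duration_s: float = 6.0
    iti_range_s: tuple[float, float] = (10.0, 14.0)
    fs: float = 1000.0
    lead_in_s: float = 15.0
    tail_s: float = 15.0
    # per-interval mean response amplitudes, μS
    amp_cs_plus: dict = field(
        default_factory=lambda: {"FIR": 0.5, "SIR": 0.35, "TIR": 0.8}
    )
    amp_cs_minus: dict = field(
        default_factory=lambda: {"FIR": 0.4, "SIR": 0.25, "TIR": 0.35}
    )
    habituation_rate: float = 0.03  # per presentation of the same CS
    amp_cv: float = 0.25  # lognormal sigma of trial-level amplitude jitter
    response_prob: float = 1.0
    onset_jitter_s: dict = field(
        default_factory=lambda: {"FIR": (1.4, 3.0), "SIR": (4.4, 6.0), "TIR": (1.4, 3.0)}
    )
    tau_rise_s: float = 0.75
    tau_decay_s: float = 3.0
    baseline_uS: float = 5.0
    drift_amp_uS: float = 0.3
    drift_period_s: float = 120.0
    noise_sd_uS: float = 0.005
    artifact_rate_per_min: float = 0.3
    artifact_step_uS: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.cs_duration_s <= 0:
            raise ValidationError("fs and cs_duration_s must be positive")
        if not 0 < self.iti_range_s[0] <= self.iti_range_s[1]:
            raise ValidationError(f"bad ITI range {self.iti_range_s}")
        for name in self.phases:
            if name not in self.trials_per_cs:
                raise ValidationError(f"no trial count for phase {name!r}")
        if not 0 <= self.response_prob <= 1:
            raise ValidationError("response_prob must lie in [0, 1]")
        for v in (
            self.noise_sd_uS,
            self.drift_amp_uS,
            self.artifact_rate_per_min,
            self.amp_cv,
            self.habituation_rate,
        ):
            if v < 0:
                raise ValidationError("rates, noise and drift must be >= 0")

    def noise_free(self) -> "SimDesign":
        """Same design with noise, drift and artifacts switched off."""
        return replace(
            self, noise_sd_uS=0.0, drift_amp_uS=0.0, artifact_rate_per_min=0.0
        )

    @property
    def n_trials(self) -> int:
        return 2 * sum(self.trials_per_cs[p] for p in self.phases)


@dataclass
class GroundTruth:
    """Per trial × interval truth table.

    Columns: event_index, phase, condition, interval, onset_s (programmed
    response onset, absolute; NaN for non-responses), injected_uS,
    amplitude_uS (realized), trough_time_s, trough_value_uS, peak_time_s,
    peak_value_uS (all realized on the preprocessed clean composite).
    """

    table: pd.DataFrame

    def amplitudes(self) -> pd.Series:
        return self.table.set_index(["event_index", "interval"])["amplitude_uS"]

    def condition_of(self) -> dict[int, str]:
        per_event = self.table.drop_duplicates("event_index")
        return dict(zip(per_event["event_index"], per_event["condition"]))

    def to_records(self, rater: str = "truth") -> list[ScoreRecord]:
        out = []
        for row in self.table.itertuples():
            if row.amplitude_uS > 0:
                out.append(
                    ScoreRecord(
                        row.event_index,
                        row.interval,
                        row.trough_time_s,
                        row.trough_value_uS,
                        row.peak_time_s,
                        row.peak_value_uS,
                        row.amplitude_uS,
                        "auto",
                        rater,
                    )
                )
            else:
                out.append(
                    ScoreRecord(
                        row.event_index, row.interval, None, None, None, None,
                        0.0, "zero", rater,
                    )
                )
        return out


def scr_kernel(
    t: np.ndarray,
    t_onset: float,
    amplitude: float,
    tau_rise_s: float = 0.75,
    tau_decay_s: float = 3.0,
) -> np.ndarray:
    """Peak-normalised biexponential SCR: a rise to ``amplitude`` followed
    by a long decay tail; identically zero before onset and for amplitude 0.

    With the default time constants the peak lags onset by
    ln(τd/τr)·τrτd/(τd−τr) ≈ 1.39 s.
    """
    if amplitude < 0:
        raise ValidationError(f"amplitude must be >= 0, got {amplitude}")
    t = np.asarray(t, dtype=float)
    if amplitude == 0:
        return np.zeros_like(t)
    dt = t - t_onset
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = np.exp(-dt[pos] / tau_decay_s) - np.exp(-dt[pos] / tau_rise_s)
    t_peak = np.log(tau_decay_s / tau_rise_s) * tau_rise_s * tau_decay_s / (
        tau_decay_s - tau_rise_s
    )
    norm = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return out * (amplitude / norm)


def kernel_peak_lag(tau_rise_s: float = 0.75, tau_decay_s: float = 3.0) -> float:
    """Closed-form onset→peak latency of the biexponential kernel."""
    return (
        np.log(tau_decay_s / tau_rise_s)
        * tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
    )


def _programme_trials(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Trial sequence with onsets, conditions and programmed responses."""
    rows = []
    t = design.lead_in_s
    event_index = 0
    windows = IntervalConfig(cs_duration_s=design.cs_duration_s).windows()
    seen = {"CS+": 0, "CS-": 0}  # presentations of each CS across phases
    for phase in design.phases:
        n = design.trials_per_cs[phase]
        conditions = ["CS+"] * n + ["CS-"] * n
        rng.shuffle(conditions)
        for cond in conditions:
            event_index += 1
            presentation = seen[cond]
            seen[cond] += 1
            base = design.amp_cs_plus if cond == "CS+" else design.amp_cs_minus
            for interval in ("FIR", "SIR", "TIR"):
                lo, hi = design.onset_jitter_s[interval]
                if interval == "TIR":
                    lo, hi = design.cs_duration_s + lo, design.cs_duration_s + hi
                onset_rel = rng.uniform(lo, hi)
                responds = rng.random() < design.response_prob
                amp = 0.0
                if responds:
                    amp = (
                        base[interval]
                        * np.exp(-design.habituation_rate * presentation)
                        * rng.lognormal(mean=0.0, sigma=design.amp_cv)
                    )
                rows.append(
                    {
                        "event_index": event_index,
                        "phase": phase,
                        "condition": cond,
                        "interval": interval,
                        "cs_onset_s": t,
                        "onset_s": t + onset_rel if amp > 0 else np.nan,
                        "injected_uS": amp,
                        "window_start_s": windows[interval][0],
                        "window_end_s": windows[interval][1],
                    }
                )
            t += design.cs_duration_s + rng.uniform(*design.iti_range_s)
    return pd.DataFrame(rows)


def _pair_max(
    x: np.ndarray,
    fs: float,
    window: tuple[float, float],
    horizon_s: float,
    threshold: float,
) -> tuple[int, int] | None:
    """Best trough→peak pair on a clean trace via scipy.signal.find_peaks."""
    peaks, _ = find_peaks(x, prominence=threshold)
    troughs, _ = find_peaks(-x, prominence=threshold)
    if x.size > 1 and x[0] == np.min(x[: max(2, int(fs))]):
        troughs = np.unique(np.append(troughs, 0))
    ws, we = window
    troughs = [i for i in troughs if ws <= i / fs < we]
    peaks = [j for j in peaks if j / fs <= we + horizon_s + 1e-9]
    best, best_amp = None, -np.inf
    for i in troughs:
        for j in peaks:
            if j <= i:
                continue
            amp = x[j] - x[i]
            if amp >= threshold and amp > best_amp:
                best, best_amp = (i, j), amp
    return best


def _measure_truth(
    truth: pd.DataFrame,
    phasic: np.ndarray,
    design: SimDesign,
    preproc: PreprocConfig,
    scoring: IntervalConfig,
) -> pd.DataFrame:
    """Realized trough/peak of each programmed response on the clean
    composite, preprocessed exactly as the scorer will see it."""
    fs = design.fs
    clean = (
        highpass(phasic, fs, preproc) if preproc.hp_cutoff_hz is not None else phasic
    )
    target = preproc.target_fs_hz
    cols = {
        "amplitude_uS": [],
        "trough_time_s": [],
        "trough_value_uS": [],
        "peak_time_s": [],
        "peak_value_uS": [],
    }
    for (event_index, cs_onset), group in truth.groupby(
        ["event_index", "cs_onset_s"], sort=True
    ):
        start = int(round(cs_onset * fs))
        stop = min(start + int(round(preproc.segment_len_s * fs)), phasic.size)
        seg = resample_mean(clean[start:stop], fs, target)
        for row in group.itertuples():
            if not row.injected_uS > 0:
                cols["amplitude_uS"].append(0.0)
                for c in list(cols)[1:]:
                    cols[c].append(np.nan)
                continue
            pair = _pair_max(
                seg,
                target,
                (row.window_start_s, row.window_end_s),
                scoring.peak_horizon_s,
                scoring.threshold_uS,
            )
            if pair is None:
                cols["amplitude_uS"].append(0.0)
                for c in list(cols)[1:]:
                    cols[c].append(np.nan)
                continue
            i, j = pair
            cols["amplitude_uS"].append(float(seg[j] - seg[i]))
            cols["trough_time_s"].append(cs_onset + i / target)
            cols["trough_value_uS"].append(float(seg[i]))
            cols["peak_time_s"].append(cs_onset + j / target)
            cols["peak_value_uS"].append(float(seg[j]))
    out = truth.copy()
    for c, v in cols.items():
        out[c] = v
    return out


def simulate_session(
    design: SimDesign,
    preproc: PreprocConfig | None = None,
    scoring: IntervalConfig | None = None,
) -> tuple[RecordingSession, GroundTruth]:
    """Render a session trace and its ground truth. Fully seed-determined."""
    preproc = preproc or PreprocConfig()
    scoring = scoring or IntervalConfig(cs_duration_s=design.cs_duration_s)
    rng = np.random.default_rng(design.seed)
    truth = _programme_trials(design, rng)
    last_onset = truth["cs_onset_s"].max()
    duration = last_onset + design.cs_duration_s + design.tail_s
    n = int(round(duration * design.fs))
    t = np.arange(n) / design.fs

    phasic = np.zeros(n)
    for row in truth.itertuples():
        if row.injected_uS > 0:
            i0 = int(row.onset_s * design.fs)
            span = slice(i0, min(n, i0 + int(30 * design.fs)))
            phasic[span] += scr_kernel(
                t[span],
                row.onset_s,
                row.injected_uS,
                design.tau_rise_s,
                design.tau_decay_s,
            )

    sc = design.baseline_uS + phasic
    if design.drift_amp_uS > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        sc = sc + design.drift_amp_uS * np.sin(
            2 * np.pi * t / design.drift_period_s + phase0
        )
    if design.noise_sd_uS > 0:
        sc = sc + rng.normal(0.0, design.noise_sd_uS, size=n)
    if design.artifact_rate_per_min > 0:
        n_art = rng.poisson(design.artifact_rate_per_min * duration / 60.0)
        for _ in range(n_art):
            i0 = rng.integers(0, n)
            sc[i0:] += rng.uniform(-1, 1) * design.artifact_step_uS

    resp = 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    cs_onsets = truth.drop_duplicates("event_index")
    events = [
        EventMarker(int(r.event_index), float(r.cs_onset_s), str(r.condition))
        for r in cs_onsets.itertuples()
    ]
    session = RecordingSession(
        sc=sc,
        fs=design.fs,
        events=events,
        resp=resp,
        meta={"generator": "scrscore.simulate", "seed": design.seed},
    )
    truth = _measure_truth(truth, phasic, design, preproc, scoring)
    return session, GroundTruth(table=truth)


def simulate_rater(
    truth: GroundTruth,
    rater_noise_sd: float = 0.03,
    miss_rate: float = 0.0,
    seed: int = 0,
    rater: str = "sim",
) -> list[ScoreRecord]:
    """Perturb realized truth amplitudes into one simulated rater's scores.

    Every target receives additive Gaussian measurement noise (a negative
    perturbed amplitude is not a scoreable rise, so it clips to a
    non-response); a fraction ``miss_rate`` of targets is zeroed
    outright. With zero noise and zero miss rate the rater reproduces
    the truth exactly.
    """
    if rater_noise_sd < 0 or not 0 <= miss_rate <= 1:
        raise ValidationError("rater_noise_sd >= 0 and miss_rate in [0, 1] required")
    rng = np.random.default_rng(seed)
    out: list[ScoreRecord] = []
    if miss_rate >= 1:
        log.warning("simulate_rater: miss_rate 1 zeroes every score")
    for row in truth.table.itertuples():
        amp = row.amplitude_uS
        if rater_noise_sd > 0:
            amp = max(amp + rng.normal(0.0, rater_noise_sd), 0.0)
        if rng.random() < miss_rate:
            amp = 0.0
        if amp > 0:
            if np.isfinite(row.trough_time_s):
                trough_t, trough_v = row.trough_time_s, row.trough_value_uS
                peak_t = row.peak_time_s
            else:
                # a non-response the rater nonetheless scored: place the
                # marks at the window opening
                trough_t = row.cs_onset_s + row.window_start_s
                trough_v = 0.0
                peak_t = trough_t + 1.0
            out.append(
                ScoreRecord(
                    row.event_index,
                    row.interval,
                    trough_t,
                    trough_v,
                    peak_t,
                    trough_v + amp,
                    amp,
                    "auto",
                    rater,
                )
            )
        else:
            out.append(
                ScoreRecord(
                    row.event_index, row.interval, None, None, None, None,
                    0.0, "zero", rater,
                )
            )
    return out


# ---------------------------------------------------------------------------
# session writers (the simulator emits the formats signal_io reads)


def _marker_channel(session: RecordingSession, cs_duration_s: float) -> np.ndarray:
    marker = np.zeros(len(session.sc))
    for ev in session.events:
        i0 = int(round(ev.onset_s * session.fs))
        i1 = min(len(marker), i0 + int(round(cs_duration_s * session.fs)))
        marker[i0:i1] = 5.0
    return marker


def write_session_text(
    session: RecordingSession, path: str | Path, cs_duration_s: float = 6.0
) -> None:
    """Columnar text: one column per channel (sc, resp, marker), header row."""
    df = pd.DataFrame(
        {
            "sc": session.sc,
            "resp": session.resp
            if session.resp is not None
            else np.zeros(len(session.sc)),
            "marker": _marker_channel(session, cs_duration_s),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def write_session_mat(
    session: RecordingSession,
    path: str | Path,
    dialect: str = "v5",
    cs_duration_s: float = 6.0,
) -> None:
    """MAT-file with sc/resp/marker vectors and a scalar fs.

    dialect "v5" is the classic format (scipy); "v7.3" the HDF5-based one.
    """
    marker = _marker_channel(session, cs_duration_s)
    resp = session.resp if session.resp is not None else np.zeros(len(session.sc))
    if dialect == "v5":
        import scipy.io

        scipy.io.savemat(
            path,
            {
                "sc": session.sc,
                "resp": resp,
                "marker": marker,
                "fs": float(session.fs),
            },
        )
    elif dialect == "v7.3":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("sc", data=session.sc)
            f.create_dataset("resp", data=resp)
            f.create_dataset("marker", data=marker)
            f.create_dataset("fs", data=np.array([float(session.fs)]))
    else:
        raise ValidationError(f"unknown MAT dialect {dialect!r}")


__all__ = [
    "PHASES",
    "SimDesign",
    "GroundTruth",
    "scr_kernel",
    "kernel_peak_lag",
    "simulate_session",
    "simulate_rater",
    "write_session_text",
    "write_session_mat",
]
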