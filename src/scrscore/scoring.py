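"""Trough-to-peak SCR detection in FIR/SIR/TIR latency windows.

The detector is a single left-to-right scan with a running extremum (the
classic delta-prominence peak walker): a peak is confirmed once the trace
has dropped at least ``threshold`` μS below the running maximum, a trough
once it has risen at least ``threshold`` above the running minimum, and
confirmed extrema alternate. The scan starts undetermined, so a segment
that opens mid-rise yields its first sample as a trough (logged, since
such records deserve a human look).

A latency window claims a response by its *onset*: among validated
(trough, later peak) pairs whose trough time falls in the half-open
window [start, end), the pair with maximal amplitude is retained — the
most prominent peak with its deepest preceding trough. The peak itself
may complete up to ``peak_horizon_s`` after the window closes (but never
past the segment, which is already clipped at the next trial). Windows
with no qualifying pair are non-responses, scored 0; windows that fall
off truncated data are marked missing/artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from .errors import ValidationError
from .io import RecordingSession, ScoreRecord, interval_rank
from .preprocess import PreprocConfig, Segment, preprocess_session

log = logging.getLogger(__name__)


@dataclass
class IntervalConfig:
    """Scoring parameters.

    threshold_uS: minimum trough-to-peak rise (and extremum validation
        delta) for a response; the classic 0.02 μS by default.
    cs_duration_s: CS length; anchors the TIR window at CS offset.
    fir/sir window: [start, end) in seconds after CS onset.
    tir_window_s: [start, end) in seconds after CS *offset*.
    peak_horizon_s: how far past a window's end the matching peak may fall.
    """

    threshold_uS: float = 0.02
    cs_duration_s: float = 6.0
    fir_window_s: tuple[float, float] = (1.0, 4.0)
    sir_window_s: tuple[float, float] = (4.0, 7.0)
    tir_window_s: tuple[float, float] = (1.0, 4.0)
    peak_horizon_s: float = 4.0

    def __post_init__(self) -> None:
        if not self.threshold_uS > 0:
            raise ValidationError(f"threshold_uS must be > 0, got {self.threshold_uS}")
        if self.peak_horizon_s < 0:
            raise ValidationError(
                f"peak_horizon_s must be >= 0, got {self.peak_horizon_s}"
            )
        if self.cs_duration_s <= 0:
            raise ValidationError(
                f"cs_duration_s must be > 0, got {self.cs_duration_s}"
            )
        w = self.windows()
        for name, (a, b) in w.items():
            if not a < b:
                raise ValidationError(f"{name} window {a}:{b} is empty or reversed")
        if not (w["FIR"][1] <= w["SIR"][0] and w["SIR"][1] <= w["TIR"][0]):
            raise ValidationError(
                f"windows must be ordered and non-overlapping on the trial "
                f"timeline, got {w}"
            )

    def windows(self) -> dict[str, tuple[float, float]]:
        """All three windows in seconds relative to CS onset."""
        off = self.cs_duration_s
        return {
            "FIR": self.fir_window_s,
            "SIR": self.sir_window_s,
            "TIR": (off + self.tir_window_s[0], off + self.tir_window_s[1]),
        }


class Extremum(NamedTuple):
    kind: str  # "peak" | "trough"
    idx: int
    value: float


@dataclass(frozen=True)
class Candidate:
    """A validated trough→peak pair within one segment."""

    trough_idx: int
    peak_idx: int
    trough_val: float
    peak_val: float

    @property
    def amplitude(self) -> float:
        return self.peak_val - self.trough_val


def find_extrema(values, threshold: float) -> list[Extremum]:
    """Alternating delta-validated local extrema of a series.

    A peak is kept only once the trace drops ≥ threshold below it before
    exceeding it; a trough once the trace rises ≥ threshold above it.
    On a tied plateau the peak takes the earliest sample (first time the
    maximum is reached) and the trough the latest (the response onset:
    where the rise leaves the minimum). The first sample may anchor the
    sequence (a segment already rising at its start yields an initial
    trough at index 0); a trailing unconfirmed extremum is discarded.
    A flat or monotone sub-threshold series yields an empty list.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    v = [float(x) for x in values]
    if len(v) < 3:
        return []
    out: list[Extremum] = []
    mx = mn = v[0]
    mxi = mni = 0
    look: str | None = None  # None until the first confirmation
    for i in range(1, len(v)):
        x = v[i]
        if x > mx:
            mx, mxi = x, i
        if x <= mn:
            mn, mni = x, i
        # confirmations are phrased as differences (mx - x, x - mn) so
        # they agree bit-for-bit with amplitude = peak - trough >= threshold
        if look is None:
            if mx - x >= threshold:
                out.append(Extremum("peak", mxi, mx))
                mn, mni = x, i
                look = "trough"
            elif x - mn >= threshold:
                out.append(Extremum("trough", mni, mn))
                mx, mxi = x, i
                look = "peak"
        elif look == "peak":
            if mx - x >= threshold:
                out.append(Extremum("peak", mxi, mx))
                mn, mni = x, i
                look = "trough"
        else:
            if x - mn >= threshold:
                out.append(Extremum("trough", mni, mn))
                mx, mxi = x, i
                look = "peak"
    return out


def _zero(event_index: int, interval: str, rater: str) -> ScoreRecord:
    return ScoreRecord(event_index, interval, None, None, None, None, 0.0, "zero", rater)


def _missing(event_index: int, interval: str, rater: str) -> ScoreRecord:
    return ScoreRecord(
        event_index, interval, None, None, None, None, 0.0, "missing_artifact", rater
    )


def best_candidate(
    extrema: list[Extremum],
    fs: float,
    window: tuple[float, float],
    cfg: IntervalConfig,
) -> Candidate | None:
    """Maximal-amplitude validated pair with the trough inside the window.

    Ties go to the earlier trough, then the earlier peak.
    """
    start_s, end_s = window
    max_peak_t = end_s + cfg.peak_horizon_s + 1e-9
    troughs = [
        e for e in extrema if e.kind == "trough" and start_s <= e.idx / fs < end_s
    ]
    peaks = [e for e in extrema if e.kind == "peak" and e.idx / fs <= max_peak_t]
    best: Candidate | None = None
    for t in troughs:
        for p in peaks:
            if p.idx <= t.idx:
                continue
            amp = p.value - t.value
            if amp < cfg.threshold_uS:
                continue
            cand = Candidate(t.idx, p.idx, t.value, p.value)
            if (
                best is None
                or amp > best.amplitude
                or (
                    amp == best.amplitude
                    and (t.idx, p.idx) < (best.trough_idx, best.peak_idx)
                )
            ):
                best = cand
    return best


def score_interval(
    seg: Segment,
    interval: str,
    window: tuple[float, float],
    cfg: IntervalConfig,
    rater: str = "auto",
) -> ScoreRecord:
    """Score one latency window of one (preprocessed, 50 Hz) segment."""
    start_s, end_s = window
    if end_s > seg.duration_s + 1e-9:
        log.debug(
            "event %d %s: window [%g, %g) falls off %.2f s of data -> missing",
            seg.event_index,
            interval,
            start_s,
            end_s,
            seg.duration_s,
        )
        return _missing(seg.event_index, interval, rater)
    extrema = find_extrema(seg.values, cfg.threshold_uS)
    cand = best_candidate(extrema, seg.fs, window, cfg)
    if cand is None:
        return _zero(seg.event_index, interval, rater)
    if cand.trough_idx == 0:
        log.debug(
            "event %d %s: segment's first sample used as trough flank",
            seg.event_index,
            interval,
        )
    return ScoreRecord(
        event_index=seg.event_index,
        interval=interval,
        trough_time_s=seg.t0_s + cand.trough_idx / seg.fs,
        trough_value_uS=cand.trough_val,
        peak_time_s=seg.t0_s + cand.peak_idx / seg.fs,
        peak_value_uS=cand.peak_val,
        amplitude_uS=cand.amplitude,
        status="auto",
        rater=rater,
    )


def score_segment(
    seg: Segment, cfg: IntervalConfig, rater: str = "auto"
) -> list[ScoreRecord]:
    """FIR, SIR and TIR records for one preprocessed segment."""
    return [
        score_interval(seg, name, window, cfg, rater)
        for name, window in cfg.windows().items()
    ]


def score_session(
    session: RecordingSession,
    preproc: PreprocConfig | None = None,
    cfg: IntervalConfig | None = None,
    rater: str = "auto",
) -> list[ScoreRecord]:
    """Score a whole session: exactly three records per event.

    Deterministic: identical inputs and configuration give identical
    records (and therefore byte-identical annotation files).
    """
    cfg = cfg or IntervalConfig()
    records: list[ScoreRecord] = []
    for seg in preprocess_session(session, preproc):
        records.extend(score_segment(seg, cfg, rater))
    return records


@dataclass(frozen=True)
class Override:
    """A programmatic manual adjustment of one (event, interval) record.

    Either set ``status`` to "zero"/"missing_artifact" to null the record,
    or supply all four coordinates to move trough/peak (status becomes
    "adjusted", amplitude is recomputed).
    """

    event_index: int
    interval: str
    status: str | None = None
    trough_time_s: float | None = None
    trough_value_uS: float | None = None
    peak_time_s: float | None = None
    peak_value_uS: float | None = None


def apply_overrides(
    records: list[ScoreRecord], overrides: Iterable[Override]
) -> list[ScoreRecord]:
    """Return a new record list with the given adjustments applied."""
    by_key = {(r.event_index, r.interval): i for i, r in enumerate(records)}
    out = list(records)
    for ov in overrides:
        key = (ov.event_index, ov.interval)
        if key not in by_key:
            raise ValidationError(
                f"override references event {ov.event_index} {ov.interval}, "
                "which is not among the scored records"
            )
        old = out[by_key[key]]
        if ov.status in ("zero", "missing_artifact"):
            new = replace(
                old,
                trough_time_s=None,
                trough_value_uS=None,
                peak_time_s=None,
                peak_value_uS=None,
                amplitude_uS=0.0,
                status=ov.status,
            )
        elif ov.status is None:
            coords = (
                ov.trough_time_s,
                ov.trough_value_uS,
                ov.peak_time_s,
                ov.peak_value_uS,
            )
            if any(c is None for c in coords):
                raise ValidationError(
                    f"override for event {ov.event_index} {ov.interval} must "
                    "either set status or supply all four coordinates"
                )
            if not ov.trough_time_s < ov.peak_time_s:
                raise ValidationError(
                    f"override for event {ov.event_index} {ov.interval}: "
                    f"trough time {ov.trough_time_s} must precede peak time "
                    f"{ov.peak_time_s}"
                )
            new = replace(
                old,
                trough_time_s=ov.trough_time_s,
                trough_value_uS=ov.trough_value_uS,
                peak_time_s=ov.peak_time_s,
                peak_value_uS=ov.peak_value_uS,
                amplitude_uS=ov.peak_value_uS - ov.trough_value_uS,
                status="adjusted",
            )
        else:
            raise ValidationError(
                f"override status must be 'zero' or 'missing_artifact', "
                f"got {ov.status!r}"
            )
        new.validate()
        out[by_key[key]] = new
    return out


def sort_records(records: list[ScoreRecord]) -> list[ScoreRecord]:
    return sorted(records, key=lambda r: (r.event_index, interval_rank(r.interval)))


__all__ = [
    "IntervalConfig",
    "Extremum",
    "Candidate",
    "Override",
    "find_extrema",
    "best_candidate",
    "score_interval",
    "score_segment",
    "score_session",
    "apply_overrides",
    "sort_records",
]
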