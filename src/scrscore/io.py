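"""Session data model and annotation file I/O.

A recording is a set of equally long channel vectors sampled at a common
rate: skin conductance (μS, required), an event-marker channel or onset-time
vector (required), and optionally respiration. MAT-files in both the classic
(v5) and HDF5-based (v7.3) dialects are accepted, as is a plain columnar
text/CSV format (one column per channel, header row, rate supplied by the
caller). No vendor struct layout is assumed: the caller names the variables
via a role→name channel map.

Score annotations are exchanged as a flat CSV, one row per trial × latency
interval, which doubles as the manual-adjustment surface: edit the file (or
use :func:`scrscore.scoring.apply_overrides`) and feed it back in.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import scipy.io

from .errors import ConfigurationError, ParseError, ValidationError

log = logging.getLogger(__name__)

#: Canonical latency-interval order (first, second, third interval response).
INTERVALS = ("FIR", "SIR", "TIR")

#: Allowed values of ScoreRecord.status.
STATUSES = ("auto", "adjusted", "zero", "missing_artifact")

SCORE_COLUMNS = (
    "event_index",
    "interval",
    "trough_time_s",
    "trough_value_uS",
    "peak_time_s",
    "peak_value_uS",
    "amplitude_uS",
    "status",
    "rater",
)


@dataclass(frozen=True)
class EventMarker:
    """One stimulus (CS) onset.

    index is the 1-based trial number; onset_s the time of CS onset in
    seconds from recording start; label an optional condition string
    (e.g. "CS+", "CS-") assigned post hoc.
    """

    index: int
    onset_s: float
    label: str = ""


@dataclass
class RecordingSession:
    """A multi-channel physiological recording with event markers."""

    sc: np.ndarray
    fs: float
    events: list[EventMarker]
    resp: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sc = np.asarray(self.sc, dtype=float).ravel()
        if self.resp is not None:
            self.resp = np.asarray(self.resp, dtype=float).ravel()
        self.validate()

    @property
    def duration_s(self) -> float:
        return len(self.sc) / self.fs

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.resp is not None and len(self.resp) != len(self.sc):
            raise ValidationError(
                "channel length mismatch: sc has "
                f"{len(self.sc)} samples, resp has {len(self.resp)}"
            )
        last = -np.inf
        for ev in self.events:
            if not 0 <= ev.onset_s < self.duration_s:
                raise ValidationError(
                    f"event {ev.index} onset {ev.onset_s:.3f} s outside "
                    f"recording [0, {self.duration_s:.3f})"
                )
            if ev.onset_s <= last:
                raise ValidationError(
                    f"event onsets not strictly increasing at event {ev.index}"
                )
            last = ev.onset_s
        idx = [ev.index for ev in self.events]
        if idx != list(range(1, len(idx) + 1)):
            raise ValidationError(
                "event indices must be unique and consecutive from 1, got "
                f"{idx[:10]}{'...' if len(idx) > 10 else ''}"
            )


@dataclass
class ScoreRecord:
    """One trial × one latency interval score.

    Times are seconds from recording start; values/amplitudes in μS.
    Status semantics:

    - ``auto`` / ``adjusted``: a response; trough precedes peak and
      amplitude = peak − trough > 0.
    - ``zero``: a non-response, scored as amplitude 0 with no coordinates.
    - ``missing_artifact``: unusable interval; treated as missing (not 0)
      by the agreement statistics.
    """

    event_index: int
    interval: str
    trough_time_s: float | None
    trough_value_uS: float | None
    peak_time_s: float | None
    peak_value_uS: float | None
    amplitude_uS: float
    status: str
    rater: str

    def __post_init__(self) -> None:
        self.validate()

    @property
    def is_response(self) -> bool:
        return self.status in ("auto", "adjusted")

    def validate(self) -> None:
        if self.interval not in INTERVALS:
            raise ValidationError(
                f"unknown interval {self.interval!r}; expected one of {INTERVALS}"
            )
        if self.status not in STATUSES:
            raise ValidationError(
                f"unknown status {self.status!r}; expected one of {STATUSES}"
            )
        coords = (
            self.trough_time_s,
            self.trough_value_uS,
            self.peak_time_s,
            self.peak_value_uS,
        )
        where = f"event {self.event_index} {self.interval}"
        if self.is_response:
            if any(c is None for c in coords):
                raise ValidationError(f"{where}: response record with null coordinates")
            if not self.trough_time_s < self.peak_time_s:
                raise ValidationError(
                    f"{where}: trough time {self.trough_time_s} must precede "
                    f"peak time {self.peak_time_s}"
                )
            amp = self.peak_value_uS - self.trough_value_uS
            if not amp > 0:
                raise ValidationError(f"{where}: non-positive amplitude {amp}")
            if abs(amp - self.amplitude_uS) > 1e-4:
                raise ValidationError(
                    f"{where}: amplitude {self.amplitude_uS} inconsistent with "
                    f"peak − trough = {amp:.6f}"
                )
        else:
            if any(c is not None for c in coords):
                raise ValidationError(
                    f"{where}: {self.status} record must have null coordinates"
                )
            if self.amplitude_uS != 0:
                raise ValidationError(
                    f"{where}: {self.status} record must have amplitude 0"
                )


def interval_rank(interval: str) -> int:
    return INTERVALS.index(interval)


# ---------------------------------------------------------------------------
# session readers


def rising_edges(marker: np.ndarray, threshold: float) -> np.ndarray:
    """Sample indices where the marker channel crosses up through threshold.

    A channel already at/above threshold at sample 0 yields an edge at 0
    (an event at the very start is emitted and left to the user to drop).
    """
    above = np.asarray(marker, dtype=float) >= threshold
    edges = above & ~np.concatenate(([False], above[:-1]))
    return np.flatnonzero(edges)


def _load_mat_variables(path: Path) -> dict[str, np.ndarray]:
    """Numeric variables from a MAT-file, either dialect, flattened."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    out: dict[str, np.ndarray] = {}
    if magic.startswith(b"\x89HDF"):
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset) and obj.dtype.kind in "fiu":
                    out[name.split("/")[-1]] = np.asarray(obj[()], dtype=float).ravel()
            f.visititems(visit)
    else:
        raw = scipy.io.loadmat(path)
        for k, v in raw.items():
            if k.startswith("__"):
                continue
            arr = np.asarray(v)
            if arr.dtype.kind in "fiu":
                out[k] = arr.astype(float).ravel()
    return out


def _load_text_columns(path: Path) -> dict[str, np.ndarray]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"could not parse {path} as columnar text: {exc}") from exc
    return {str(c): df[c].to_numpy(dtype=float) for c in df.columns}


def read_session(
    path: str | Path,
    channel_map: Mapping[str, str],
    fs: float | None = None,
    marker_threshold: float | None = None,
) -> RecordingSession:
    """Load a recording from a MAT-file (v5 or v7.3) or columnar text.

    channel_map maps roles to variable/column names; roles ``sc`` and
    ``events`` are required, ``resp`` and ``fs`` optional. The events
    variable may be a continuous marker channel (same length as sc;
    converted to onsets at rising edges, threshold defaulting to half the
    channel maximum) or a vector of onset times in seconds.

    The sampling rate is taken from the file (role ``fs``, or a variable
    literally named ``fs``) when present, else from the fs argument.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if path.suffix.lower() == ".mat":
        variables = _load_mat_variables(path)
    else:
        variables = _load_text_columns(path)

    def pull(role: str, required: bool) -> np.ndarray | None:
        name = channel_map.get(role)
        if name is None:
            if required:
                raise ConfigurationError(
                    f"channel map does not name a {role!r} channel "
                    f"(available variables: {sorted(variables)})"
                )
            return None
        if name not in variables:
            raise ConfigurationError(
                f"{role!r} channel {name!r} not found in {path.name} "
                f"(available variables: {sorted(variables)})"
            )
        return variables[name]

    sc = pull("sc", required=True)
    ev_vec = pull("events", required=True)
    resp = pull("resp", required=False)

    fs_name = channel_map.get("fs", "fs")
    if fs_name in variables and variables[fs_name].size == 1:
        fs_eff = float(variables[fs_name][0])
    elif fs is not None:
        fs_eff = float(fs)
    else:
        raise ConfigurationError(
            f"no sampling rate: {path.name} carries no {fs_name!r} variable "
            "and no fs argument was given"
        )
    if not fs_eff > 0:
        raise ValidationError(f"sampling rate must be > 0, got {fs_eff}")

    if len(ev_vec) == len(sc) and len(sc) > 1:
        thr = marker_threshold
        if thr is None:
            thr = float(np.max(ev_vec)) / 2.0
        if np.max(ev_vec) > np.min(ev_vec):
            onsets = rising_edges(ev_vec, thr) / fs_eff
        else:
            onsets = np.empty(0)
        if onsets.size == 0:
            raise ValidationError(
                "no events found on marker channel "
                f"(threshold {thr:.4g}; channel min {np.min(ev_vec):.4g}, "
                f"max {np.max(ev_vec):.4g}, mean {np.mean(ev_vec):.4g})"
            )
    else:
        onsets = np.sort(np.asarray(ev_vec, dtype=float))
        if onsets.size == 0:
            raise ValidationError("event onset vector is empty")

    events = [EventMarker(i + 1, float(t)) for i, t in enumerate(onsets)]
    return RecordingSession(
        sc=sc,
        fs=fs_eff,
        events=events,
        resp=resp,
        meta={"source": str(path), "channel_map": dict(channel_map)},
    )


# ---------------------------------------------------------------------------
# annotation CSV


def _fmt(value: float | None, decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_scores(records: Sequence[ScoreRecord], path: str | Path) -> None:
    """Write annotations as CSV (UTF-8, LF), sorted by (event, interval)."""
    if not records:
        raise ValidationError("no score records to write")
    seen: set[tuple] = set()
    for r in records:
        key = (r.event_index, r.interval, r.rater)
        if key in seen:
            raise ValidationError(f"duplicate score record for {key}")
        seen.add(key)
    ordered = sorted(
        records, key=lambda r: (r.rater, r.event_index, interval_rank(r.interval))
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SCORE_COLUMNS)
        for r in ordered:
            writer.writerow(
                [
                    r.event_index,
                    r.interval,
                    _fmt(r.trough_time_s, 4),
                    _fmt(r.trough_value_uS, 6),
                    _fmt(r.peak_time_s, 4),
                    _fmt(r.peak_value_uS, 6),
                    f"{r.amplitude_uS:.6f}",
                    r.status,
                    r.rater,
                ]
            )


def read_scores(path: str | Path) -> list[ScoreRecord]:
    """Read an annotation CSV back into validated records."""
    path = Path(path)
    records: list[ScoreRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != SCORE_COLUMNS:
            raise ParseError(
                f"{path.name}: header mismatch; expected {','.join(SCORE_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SCORE_COLUMNS):
                raise ParseError(
                    f"{path.name} row {lineno}: expected "
                    f"{len(SCORE_COLUMNS)} cells, got {len(row)}"
                )
            cells = dict(zip(SCORE_COLUMNS, row))

            def num(col: str, lineno=lineno, cells=cells) -> float | None:
                cell = cells[col].strip()
                if cell == "":
                    return None
                try:
                    return float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} row {lineno}, column {col!r}: "
                        f"malformed numeric cell {cell!r}"
                    ) from exc

            try:
                event_index = int(cells["event_index"])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} row {lineno}, column 'event_index': "
                    f"malformed integer {cells['event_index']!r}"
                ) from exc
            interval = cells["interval"].strip()
            if interval not in INTERVALS:
                raise ParseError(
                    f"{path.name} row {lineno}: unknown interval {interval!r}"
                )
            amplitude = num("amplitude_uS")
            if amplitude is None:
                raise ParseError(
                    f"{path.name} row {lineno}: amplitude_uS may not be empty"
                )
            try:
                records.append(
                    ScoreRecord(
                        event_index=event_index,
                        interval=interval,
                        trough_time_s=num("trough_time_s"),
                        trough_value_uS=num("trough_value_uS"),
                        peak_time_s=num("peak_time_s"),
                        peak_value_uS=num("peak_value_uS"),
                        amplitude_uS=amplitude,
                        status=cells["status"].strip(),
                        rater=cells["rater"].strip(),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} row {lineno}: {exc}") from exc
    return records


__all__ = [
    "EventMarker",
    "RecordingSession",
    "ScoreRecord",
    "INTERVALS",
    "STATUSES",
    "SCORE_COLUMNS",
    "interval_rank",
    "rising_edges",
    "read_session",
    "write_scores",
    "read_scores",
]
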