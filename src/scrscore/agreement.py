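"""Rater-agreement statistics: one-way agreement ICC, Bland–Altman,
and Pareto tabulation of discrepancy causes.

The ICC is the one-way random-effects agreement form, ICC(1): targets
(trials or participant averages) are random rows, the rater effect is
absorbed into error, so both random and systematic rater differences
lower the coefficient. With mean squares from the one-way ANOVA,

    ICC(1) = (MSB − MSW) / (MSB + (k − 1) · MSW),   F = MSB / MSW

on (n − 1, n(k − 1)) degrees of freedom for n targets × k raters.

Bland–Altman agreement limits are mean(d) ± 1.96 · SD(d) on the paired
differences d = a − b (sample SD, n − 1); scores outside the limits are
the discrepant pairs handed to the Pareto step. The narrower CI of the
mean difference is also reported but not used for outlier flagging, which
needs a dispersion band. Non-responses count as amplitude 0 throughout;
missing/artifact records are dropped pairwise before any statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import ScoreRecord, interval_rank

log = logging.getLogger(__name__)


@dataclass
class ICCResult:
    icc: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    ms_between: float
    ms_within: float
    n_targets: int
    k_raters: int


def icc_oneway(x: np.ndarray) -> ICCResult:
    """Agreement ICC(1) and its F test for an n × k score matrix.

    Rows are targets, columns raters; no missing cells (drop incomplete
    rows first, e.g. via :func:`trial_matrix`). A matrix with zero total
    variance (all cells identical) is perfect agreement: ICC = 1 with a
    warning, F undefined (inf).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"score matrix must be 2-D, got shape {x.shape}")
    n, k = x.shape
    if n < 3:
        raise ValidationError(f"need at least 3 targets for an ICC, got {n}")
    if k < 2:
        raise ValidationError(f"need at least 2 raters for an ICC, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("score matrix contains non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssw = float(((x - row_means[:, None]) ** 2).sum())
    df1 = n - 1
    df2 = n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    if msb == 0.0 and msw == 0.0:
        log.warning("icc_oneway: zero between- and within-target variance; ICC := 1")
        return ICCResult(1.0, math.inf, df1, df2, 0.0, 0.0, 0.0, n, k)
    if msw == 0.0:
        return ICCResult(1.0, math.inf, df1, df2, 0.0, msb, 0.0, n, k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    p = float(stats.f.sf(f, df1, df2))
    return ICCResult(float(icc), float(f), df1, df2, p, msb, msw, n, k)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    limits: tuple[float, float]
    ci_mean: tuple[float, float]
    n: int
    outliers: list[tuple[int, float, float]]  # (pair index, difference, pair mean)

    @property
    def outlier_fraction(self) -> float:
        return len(self.outliers) / self.n


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Limits-of-agreement analysis of two paired score vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError(
            f"paired vectors differ in length: {a.size} vs {b.size}"
        )
    if a.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {a.size}")
    d = a - b
    m = (a + b) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    lo, hi = mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d
    half_ci = 1.96 * sd_d / math.sqrt(d.size)
    outliers = [
        (int(i), float(d[i]), float(m[i]))
        for i in np.flatnonzero((d < lo) | (d > hi))
    ]
    return BlandAltmanResult(
        mean_diff=mean_d,
        sd_diff=sd_d,
        limits=(float(lo), float(hi)),
        ci_mean=(mean_d - half_ci, mean_d + half_ci),
        n=int(d.size),
        outliers=outliers,
    )


def bland_altman_plot(a: np.ndarray, b: np.ndarray, path) -> BlandAltmanResult:
    """Difference-vs-mean plot with mean and agreement-limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.6)
    ax.axhline(res.mean_diff, ls=":", color="k", label="mean difference")
    for lim in res.limits:
        ax.axhline(lim, lw=2, color="tab:red")
    ax.set_xlabel("mean SCR amplitude (μS)")
    ax.set_ylabel("difference (μS)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


# ---------------------------------------------------------------------------
# building score matrices from records


def _amplitude_or_nan(r: ScoreRecord) -> float:
    return math.nan if r.status == "missing_artifact" else r.amplitude_uS


def trial_matrix(
    record_sets: list[list[ScoreRecord]],
) -> tuple[list[tuple[int, str]], np.ndarray]:
    """Trial-by-trial n × k matrix over (event, interval) targets.

    Each element of record_sets is one rater's records for the same
    session. Targets missing (or marked missing_artifact) for any rater
    are dropped pairwise-complete with a logged count.
    """
    if len(record_sets) < 2:
        raise ValidationError("need at least two record sets")
    maps = []
    for records in record_sets:
        maps.append(
            {(r.event_index, r.interval): _amplitude_or_nan(r) for r in records}
        )
    keys = sorted(
        set.intersection(*(set(m) for m in maps)),
        key=lambda k: (k[0], interval_rank(k[1])),
    )
    rows, ids = [], []
    dropped = 0
    for key in keys:
        vals = [m[key] for m in maps]
        if any(math.isnan(v) for v in vals):
            dropped += 1
            continue
        ids.append(key)
        rows.append(vals)
    if dropped:
        log.info("trial_matrix: dropped %d targets with missing/artifact cells", dropped)
    return ids, np.asarray(rows, dtype=float)


def average_scores(
    records: list[ScoreRecord],
    by: dict[int, str] | None = None,
) -> dict[tuple[str, str], float]:
    """Per (group, interval) mean amplitude for one rater's records.

    ``by`` maps event_index → group label (participant, phase, condition
    — whatever the analysis averages over); all events share one group
    when omitted. Zeros (non-responses) are averaged in as 0; missing/
    artifact trials are excluded; a group × interval cell whose trials are
    all missing is dropped with a warning.
    """
    if not records:
        raise ValidationError("no records to average")
    sums: dict[tuple[str, str], list[float]] = {}
    for r in records:
        group = by.get(r.event_index, "all") if by else "all"
        sums.setdefault((group, r.interval), []).append(_amplitude_or_nan(r))
    out: dict[tuple[str, str], float] = {}
    for key in sorted(sums, key=lambda k: (k[0], interval_rank(k[1]))):
        vals = [v for v in sums[key] if not math.isnan(v)]
        if not vals:
            log.warning("average_scores: %s has no usable trials; dropped", key)
            continue
        out[key] = float(np.mean(vals))
    return out


def average_matrix(
    record_sets: list[list[ScoreRecord]],
    by: dict[int, str] | None = None,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Average-score n × k matrix across raters (targets = group × interval)."""
    per_rater = [average_scores(records, by) for records in record_sets]
    keys = sorted(
        set.intersection(*(set(m) for m in per_rater)),
        key=lambda k: (k[0], interval_rank(k[1])),
    )
    mat = np.asarray([[m[k] for m in per_rater] for k in keys], dtype=float)
    return keys, mat


# ---------------------------------------------------------------------------
# Pareto discrepancy tabulation


@dataclass
class DiscrepancyTable:
    """Discrepancy categories sorted by count (ties alphabetical) with
    running cumulative percentages."""

    categories: list[tuple[str, int]]
    cumulative_pct: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.categories)
        run = 0
        self.cumulative_pct = []
        for _, c in self.categories:
            run += c
            self.cumulative_pct.append(100.0 * run / total)

    @property
    def total(self) -> int:
        return sum(c for _, c in self.categories)


def pareto(labels: list[str]) -> DiscrepancyTable:
    """Tabulate discrepancy-cause labels in Pareto order.

    Categorising the causes is human work; this only counts the supplied
    labels, sorts descending (alphabetical on ties, stable across runs)
    and accumulates percentages.
    """
    if not labels:
        raise ValidationError("no discrepancy labels supplied")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return DiscrepancyTable(categories=ordered)


__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "DiscrepancyTable",
    "icc_oneway",
    "bland_altman",
    "bland_altman_plot",
    "trial_matrix",
    "average_scores",
    "average_matrix",
    "pareto",
]
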