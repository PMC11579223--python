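"""Independent reference implementations used only by the tests.

These deliberately avoid the package's scanning algorithms: extrema are
validated sample-by-sample from the definition (a peak must drop by at
least the threshold on both sides before the trace exceeds it; mirrored
for troughs; the series start may anchor a flank), pairs are searched
exhaustively, and the ICC comes from literal one-way ANOVA sums of
squares written as loops.
"""

from __future__ import annotations

import numpy as np


def validated_peaks(v: np.ndarray, thr: float) -> list[int]:
    """Indices i that qualify as delta-validated peaks, first-of-plateau."""
    v = np.asarray(v, dtype=float)
    out = []
    for i in range(len(v)):
        # right flank: first r dropping by >= thr, nothing higher before it
        right_ok = False
        for r in range(i + 1, len(v)):
            if v[r] > v[i]:
                break
            if v[i] - v[r] >= thr:
                right_ok = True
                break
        if not right_ok:
            continue
        # left flank: last l with v[l] <= v[i] - thr and all between strictly
        # below v[i]; or the series start anchors (everything before < v[i])
        left_ok = True
        for l in range(i - 1, -1, -1):
            if v[i] - v[l] >= thr:
                break
            if v[l] >= v[i]:
                left_ok = False
                break
        if left_ok:
            out.append(i)
    return out


def validated_troughs(v: np.ndarray, thr: float) -> list[int]:
    """Indices i that qualify as delta-validated troughs, last-of-plateau
    (the sample where the rise leaves the minimum)."""
    v = np.asarray(v, dtype=float)
    out = []
    for i in range(len(v)):
        # right flank: first r rising by >= thr, everything before
        # it strictly above v[i] (so i is the last sample of its plateau)
        right_ok = False
        for r in range(i + 1, len(v)):
            if v[r] <= v[i]:
                break
            if v[r] - v[i] >= thr:
                right_ok = True
                break
        if not right_ok:
            continue
        # left flank: a rise of thr going left, or the series start;
        # equal values are allowed, strictly lower ones break the flank
        left_ok = True
        for l in range(i - 1, -1, -1):
            if v[l] - v[i] >= thr:
                break
            if v[l] < v[i]:
                left_ok = False
                break
        if left_ok:
            out.append(i)
    return out


def best_pair_bruteforce(
    v: np.ndarray,
    fs: float,
    window: tuple[float, float],
    horizon_s: float,
    thr: float,
) -> tuple[int, int, float] | None:
    """Exhaustive (trough, peak) pair search: trough in the half-open
    window, peak later and at most horizon past the window end, amplitude
    at least the threshold; maximal amplitude, ties to the earliest pair.
    Returns (trough_idx, peak_idx, amplitude) or None."""
    v = np.asarray(v, dtype=float)
    ws, we = window
    troughs = [i for i in validated_troughs(v, thr) if ws <= i / fs < we]
    peaks = [j for j in validated_peaks(v, thr) if j / fs <= we + horizon_s + 1e-9]
    best = None
    for i in troughs:
        for j in peaks:
            if j <= i:
                continue
            amp = v[j] - v[i]
            if amp < thr:
                continue
            if best is None or amp > best[2] or (amp == best[2] and (i, j) < best[:2]):
                best = (i, j, amp)
    return best


def icc1_anova(x: np.ndarray) -> tuple[float, float]:
    """One-way random-effects agreement ICC and F, from first principles."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = 0.0
    for row in x:
        for cell in row:
            grand += cell
    grand /= n * k
    ssb = 0.0
    ssw = 0.0
    for row in x:
        mean_i = sum(row) / k
        ssb += k * (mean_i - grand) ** 2
        for cell in row:
            ssw += (cell - mean_i) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw if msw > 0 else float("inf")
    return icc, f
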