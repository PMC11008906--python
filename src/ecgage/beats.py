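"""R-peak detection, per-beat fiducial delineation, NN-series construction.

Detection follows the classic Pan–Tompkins chain: 5-15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with a 200 ms refractory period; each detection is mapped back
to the raw-signal maximum within ±50 ms.

Delineation uses windowed extrema around each R peak with onsets/offsets
defined by a 10 %-of-peak amplitude rule — deterministic rules that can be
checked exactly against the Gaussian-beat generator.

NN intervals are successive R-R differences; intervals outside [300, 2000]
ms or deviating more than 20 % from an 11-beat running median are rejected,
which operationalises "normal-to-normal".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

FIDUCIAL_NAMES = (
    "P_onset", "P_peak", "P_offset", "Q", "R", "S", "T_onset", "T_peak", "T_offset",
)

NN_RANGE_MS = (300.0, 2000.0)
NN_MEDIAN_WINDOW = 11
NN_MEDIAN_TOL = 0.20
REFRACTORY_S = 0.2


class InsufficientBeatsError(ValueError):
    pass


@dataclass
class NNSeries:
    """Artifact-filtered normal-to-normal intervals.

    ``intervals_ms[i]`` ends at ``timestamps_s[i]`` (seconds from record
    start); ``n_rejected`` counts excluded intervals.
    """

    intervals_ms: np.ndarray
    timestamps_s: np.ndarray
    n_rejected: int

    def __len__(self) -> int:
        return len(self.intervals_ms)


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins-style QRS detection; returns strictly increasing sample
    indices of R peaks.  A flat signal yields an empty result."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if np.ptp(x) < 1e-12:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    b, a = butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds on the integrated signal
    spki = float(np.max(integ[: int(2 * fs)])) * 0.5 or float(np.max(integ)) * 0.5
    npki = float(np.mean(integ[: int(2 * fs)])) * 0.5
    peaks = []
    for c in cand:
        v = integ[c]
        thr1 = npki + 0.25 * (spki - npki)
        if v > thr1:
            spki = 0.125 * v + 0.875 * spki
            peaks.append(c)
        else:
            npki = 0.125 * v + 0.875 * npki
    if not peaks:
        return np.array([], dtype=int)

    # map back to the raw-signal local maximum within ±50 ms
    half = int(round(0.05 * fs))
    refined = []
    for c in peaks:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce the refractory period after refinement
    keep = [0]
    for i in range(1, len(refined)):
        if refined[i] - refined[keep[-1]] >= refractory:
            keep.append(i)
        elif x[refined[i]] > x[refined[keep[-1]]]:
            keep[-1] = i
    return refined[keep]


def _ms(fs: float, ms: float) -> int:
    return int(round(ms / 1000.0 * fs))


def _onset_offset(
    x: np.ndarray, peak: int, baseline: float, limit_lo: int, limit_hi: int
) -> tuple:
    """Nearest samples on either side of ``peak`` where the wave falls to 10 %
    of its peak-to-baseline amplitude; NaN if no crossing inside the limits."""
    limit_lo, limit_hi = int(limit_lo), int(limit_hi)
    amp = x[peak] - baseline
    thresh = abs(amp) * 0.1
    onset = np.nan
    for i in range(peak - 1, limit_lo - 1, -1):
        if abs(x[i] - baseline) <= thresh:
            onset = i
            break
    offset = np.nan
    for i in range(peak + 1, limit_hi):
        if abs(x[i] - baseline) <= thresh:
            offset = i
            break
    return onset, offset


def delineate_beats(
    signal: np.ndarray,
    fs: float,
    rpeaks: np.ndarray,
    min_wave_amp_mv: float = 0.02,
) -> pd.DataFrame:
    """Per-beat fiducial sample indices (float, NaN when absent).

    Q is the minimum in (R-80 ms, R), S the minimum in (R, R+80 ms),
    P_peak the maximum in (R-300 ms, R-100 ms), T_peak the maximum in
    (R+150 ms, min(R+450 ms, next R-100 ms)).  Windows truncated by record
    edges yield absent fiducials; P/T waves below ``min_wave_amp_mv`` above
    baseline are treated as absent.
    """
    x = np.asarray(signal, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    if len(rpeaks) < 1:
        raise ValueError("need at least one R peak")
    n = len(x)
    rows = []
    for bi, r in enumerate(rpeaks):
        row = {name: np.nan for name in FIDUCIAL_NAMES}
        row["R"] = float(r)

        # local baseline: quiet zone between the previous T wave and this P wave
        blo, bhi = r - _ms(fs, 300), r - _ms(fs, 220)
        baseline = float(np.median(x[max(0, blo) : max(1, bhi)])) if bhi > 0 else 0.0

        qlo = r - _ms(fs, 80)
        if qlo >= 0 and qlo < r:
            row["Q"] = float(qlo + np.argmin(x[qlo:r]))
        shi = r + _ms(fs, 80) + 1
        if shi <= n and r + 1 < shi:
            row["S"] = float(r + 1 + np.argmin(x[r + 1 : shi]))

        plo, phi = r - _ms(fs, 300), r - _ms(fs, 100)
        if plo >= 0:
            p_peak = plo + int(np.argmax(x[plo:phi]))
            if x[p_peak] - baseline >= min_wave_amp_mv:
                row["P_peak"] = float(p_peak)
                onset, offset = _onset_offset(x, p_peak, baseline, plo, min(n, r))
                row["P_onset"], row["P_offset"] = onset, offset

        tlo = r + _ms(fs, 150)
        thi = r + _ms(fs, 450)
        if bi + 1 < len(rpeaks):
            thi = min(thi, rpeaks[bi + 1] - _ms(fs, 100))
        if thi <= n and thi > tlo and tlo < n:
            seg = x[tlo:thi]
            t_idx = tlo + int(np.argmax(np.abs(seg - baseline)))
            if abs(x[t_idx] - baseline) >= min_wave_amp_mv:
                row["T_peak"] = float(t_idx)
                onset, offset = _onset_offset(
                    x, t_idx, baseline, max(0, row["S"] if np.isfinite(row["S"]) else tlo - _ms(fs, 60)), min(n, thi + _ms(fs, 80))
                )
                row["T_onset"], row["T_offset"] = onset, offset

        # enforce strict ordering; violating entries become absent
        order = [row[name] for name in FIDUCIAL_NAMES]
        prev = -np.inf
        for name, v in zip(FIDUCIAL_NAMES, order):
            if np.isfinite(v):
                if v <= prev:
                    row[name] = np.nan
                else:
                    prev = v
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FIDUCIAL_NAMES))


def build_nn_series(rpeaks: np.ndarray, fs: float) -> NNSeries:
    """Successive R-R differences in ms with range and running-median
    artifact rejection; raises ``InsufficientBeatsError`` when fewer than
    two intervals survive."""
    rpeaks = np.asarray(rpeaks)
    if len(rpeaks) < 3:
        raise InsufficientBeatsError("need at least 3 R peaks")
    nn = np.diff(rpeaks) / fs * 1000.0
    ts = rpeaks[1:] / fs

    runmed = (
        pd.Series(nn)
        .rolling(NN_MEDIAN_WINDOW, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    ok = (
        (nn >= NN_RANGE_MS[0])
        & (nn <= NN_RANGE_MS[1])
        & (np.abs(nn - runmed) <= NN_MEDIAN_TOL * runmed)
    )
    n_rejected = int((~ok).sum())
    if ok.sum() < 2:
        raise InsufficientBeatsError("fewer than 2 surviving NN intervals")
    return NNSeries(
        intervals_ms=nn[ok], timestamps_s=ts[ok], n_rejected=n_rejected
    )
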