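"""Long-range (HRV) and short-range (SR) ECG feature battery.

Long-range features are computed from the artifact-filtered NN series:
time-domain statistics (SDNN, RMSSD, pNN20/50, MCVNN), windowed SDNN
indices (SDANN1/SDANN5 as the *mean* of per-window SDNN values),
heart-rate fragmentation (PAS), detrended fluctuation exponents
(alpha1/alpha2 plus a multifractal alpha1 mean and spectrum width),
band powers (LF/HF) and ECG-derived respiration (breathing rate and the
standard deviation of the detrended respiration waveform).

Short-range features are per-beat morphology measurements (wave
amplitudes against a local baseline, PR/QRS/QT intervals, wave durations,
RR and heart rate) averaged over the record so both sets combine into a
single row per recording.

Missing inputs yield NaN feature values, never exceptions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch
from scipy.stats import spearmanr  # noqa: F401  (re-exported for explainability use)

from .beats import NNSeries, build_nn_series, delineate_beats, detect_r_peaks
from .records import EcgRecord

HRV_FEATURES = [
    "HRV_SDNN", "HRV_SDANN1", "HRV_SDANN5", "HRV_RMSSD", "HRV_pNN20",
    "HRV_pNN50", "HRV_MCVNN", "HRV_PAS", "HRV_alpha1", "HRV_alpha2",
    "HRV_alpha1_mean", "HRV_alpha1_fluctuation", "HRV_LF", "HRV_HF",
    "breathing_rate", "breathing_signal_sd",
]
SR_FEATURES = [
    "SR_p_mV", "SR_q_mV", "SR_r_mV", "SR_s_mV", "SR_t_mV",
    "SR_RR", "SR_heart_rate", "SR_PR", "SR_QRS", "SR_QT",
    "SR_P_duration", "SR_T_duration",
]
FEATURE_COLUMNS = HRV_FEATURES + SR_FEATURES

#: minimum alternation-segment length in NN intervals (3 successive
#: differences) for the PAS fragmentation metric
PAS_MIN_SEGMENT_INTERVALS = 4

ALPHA1_SCALES = np.unique(np.round(np.geomspace(4, 16, 8)).astype(int))
ALPHA2_SCALES = np.unique(np.round(np.geomspace(16, 64, 10)).astype(int))
# moderate q range and box sizes >= 8: strongly negative moments over
# tiny boxes are dominated by near-zero detrending residuals and make the
# singularity-spectrum width diverge even for monofractal input
MFDFA_Q = np.array([-3, -2, -1, 1, 2, 3], dtype=float)
MFDFA_SCALE_RANGE = (8, 64)


# ---------------------------------------------------------------- time domain

def time_domain_hrv(nn: NNSeries) -> dict:
    x = np.asarray(nn.intervals_ms, dtype=float)
    out = {k: np.nan for k in ("SDNN", "RMSSD", "pNN20", "pNN50", "MCVNN")}
    if len(x) >= 2:
        out["SDNN"] = float(np.std(x, ddof=1))
        d = np.diff(x)
        out["RMSSD"] = float(np.sqrt(np.mean(d**2)))
        med = float(np.median(x))
        if med != 0:
            out["MCVNN"] = float(np.median(np.abs(x - med)) / med)
    if len(x) >= 3:
        d = np.abs(np.diff(x))
        out["pNN20"] = float(100.0 * np.mean(d > 20.0))
        out["pNN50"] = float(100.0 * np.mean(d > 50.0))
    return out


def sdann_index(nn: NNSeries, window_min: float) -> float:
    """Mean of per-window SDNN over consecutive ``window_min``-minute windows
    from t=0; the trailing partial window is discarded.  NaN when fewer than
    two full windows exist."""
    w = window_min * 60.0
    ts = np.asarray(nn.timestamps_s, dtype=float)
    x = np.asarray(nn.intervals_ms, dtype=float)
    if len(ts) == 0:
        return np.nan
    n_windows = int(ts[-1] // w)
    if n_windows < 2:
        return np.nan
    sdnns = []
    for k in range(n_windows):
        mask = (ts >= k * w) & (ts < (k + 1) * w)
        if mask.sum() >= 2:
            sdnns.append(np.std(x[mask], ddof=1))
    if not sdnns:
        return np.nan
    return float(np.mean(sdnns))


def fragmentation_pas(nn: NNSeries) -> float:
    """Percentage of NN intervals inside alternation segments: maximal runs
    of successive differences with strictly alternating sign spanning at
    least ``PAS_MIN_SEGMENT_INTERVALS`` intervals.  Zero differences break
    runs."""
    x = np.asarray(nn.intervals_ms, dtype=float)
    if len(x) < 5:
        return np.nan
    d = np.diff(x)
    s = np.sign(d)
    member = np.zeros(len(x), dtype=bool)
    i = 0
    while i < len(d):
        if s[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(d) and s[j + 1] == -s[j] and s[j + 1] != 0:
            j += 1
        run_diffs = j - i + 1
        if run_diffs + 1 >= PAS_MIN_SEGMENT_INTERVALS:
            member[i : j + 2] = True
        i = j + 1
    return float(100.0 * member.mean())


# ------------------------------------------------------------------------ DFA

def _dfa_correction(n: int) -> float:
    """Finite-size correction for linear-detrended DFA at box size ``n``.

    For uncorrelated unit-variance input the expected squared fluctuation is
    tr(R L Lᵀ Rᵀ)/n, with L the cumulative-sum operator and R the residual
    projector of a linear fit; dividing F(n) by sqrt of that and multiplying
    by sqrt(n) makes white noise scale exactly as n^0.5 at small box sizes.
    """
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    R = np.eye(n) - H
    L = np.tril(np.ones((n, n)))
    M = R @ L
    expected = np.trace(M @ M.T) / n
    return float(np.sqrt(expected / n))


_DFA_CORRECTION_CACHE: dict = {}


def _dfa_correction_cached(n: int) -> float:
    if n not in _DFA_CORRECTION_CACHE:
        _DFA_CORRECTION_CACHE[n] = _dfa_correction(int(n))
    return _DFA_CORRECTION_CACHE[n]


def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray) -> tuple:
    """Per-scale per-box RMS fluctuations of the integrated, mean-centred
    series with linear detrending in non-overlapping boxes."""
    y = np.cumsum(x - np.mean(x))
    per_scale = []
    used_scales = []
    for n in scales:
        n_boxes = len(y) // n
        if n_boxes < 2:
            continue
        segs = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n, dtype=float)
        t_mean = t.mean()
        t_c = t - t_mean
        denom = np.sum(t_c**2)
        seg_mean = segs.mean(axis=1, keepdims=True)
        slope = (segs @ t_c)[:, None] / denom
        resid = segs - seg_mean - slope * t_c
        f_box = np.sqrt(np.mean(resid**2, axis=1)) / _dfa_correction_cached(n)
        per_scale.append(f_box)
        used_scales.append(n)
    return np.array(used_scales), per_scale


def dfa_alpha(nn: NNSeries) -> tuple:
    """Short-scale (4-16 beats) and long-scale (16-64 beats) DFA exponents;
    NaN when the series is too short (alpha1: <100, alpha2: <300 intervals)."""
    x = np.asarray(nn.intervals_ms, dtype=float)
    alpha1 = alpha2 = np.nan
    if len(x) >= 100:
        alpha1 = _dfa_slope(x, ALPHA1_SCALES)
    if len(x) >= 300:
        alpha2 = _dfa_slope(x, ALPHA2_SCALES)
    return alpha1, alpha2


def _dfa_slope(x: np.ndarray, scales: np.ndarray) -> float:
    used, per_scale = _dfa_fluctuations(x, scales)
    if len(used) < 2:
        return np.nan
    f = np.array([np.sqrt(np.mean(fb**2)) for fb in per_scale])
    if np.any(f <= 0):
        return np.nan
    return float(np.polyfit(np.log10(used), np.log10(f), 1)[0])


def mfdfa_summary(nn: NNSeries) -> tuple:
    """Multifractal DFA summary: generalized Hurst exponents h(q) for
    q in ±1..3 over box sizes 8 to min(64, N/8), singularity exponents
    alpha(q) = h(q) + q h'(q); returns (mean alpha, max-min alpha)."""
    x = np.asarray(nn.intervals_ms, dtype=float)
    if len(x) < 500 or np.std(x) == 0:
        return np.nan, np.nan
    lo, hi = MFDFA_SCALE_RANGE
    scales = np.unique(
        np.round(np.geomspace(lo, max(lo + 1, min(hi, len(x) // 8)), 8)).astype(int)
    )
    used, per_scale = _dfa_fluctuations(x, scales)
    if len(used) < 2:
        return np.nan, np.nan
    log_n = np.log10(used.astype(float))
    h = np.empty(len(MFDFA_Q))
    for qi, q in enumerate(MFDFA_Q):
        fq = []
        for fb in per_scale:
            fb = fb[fb > 0]
            if len(fb) == 0:
                return np.nan, np.nan
            fq.append(np.mean(fb**q) ** (1.0 / q))
        h[qi] = np.polyfit(log_n, np.log10(fq), 1)[0]
    dh = np.gradient(h, MFDFA_Q)
    alpha_q = h + MFDFA_Q * dh
    return float(np.mean(alpha_q)), float(np.max(alpha_q) - np.min(alpha_q))


# ---------------------------------------------------------------- frequency

EDR_FS = 4.0  # Hz, uniform grid for interpolated NN / respiration series


def _uniform_series(values: np.ndarray, times: np.ndarray, fs: float = EDR_FS) -> tuple:
    """Cubic interpolation onto a uniform grid spanning the timestamps."""
    if len(values) < 4 or times[-1] - times[0] <= 0:
        return None, None
    grid = np.arange(times[0], times[-1], 1.0 / fs)
    cs = CubicSpline(times, values)
    return grid, cs(grid)


def frequency_domain(nn: NNSeries) -> tuple:
    """(LF, HF) band powers in ms² from a Welch periodogram of the NN series
    interpolated to 4 Hz; NaN below 2 minutes of data."""
    ts = np.asarray(nn.timestamps_s, dtype=float)
    if len(nn) < 4 or ts[-1] - ts[0] < 120.0:
        return np.nan, np.nan
    grid, y = _uniform_series(nn.intervals_ms, ts)
    if grid is None:
        return np.nan, np.nan
    y = y - np.mean(y)
    nperseg = min(len(y), 1024)
    f, pxx = welch(y, fs=EDR_FS, nperseg=nperseg)
    lf = float(np.trapezoid(pxx[(f >= 0.04) & (f < 0.15)], f[(f >= 0.04) & (f < 0.15)]))
    hf = float(np.trapezoid(pxx[(f >= 0.15) & (f < 0.40)], f[(f >= 0.15) & (f < 0.40)]))
    return lf, hf


def edr_breathing(signal: np.ndarray, rpeaks: np.ndarray, fs: float) -> tuple:
    """ECG-derived respiration from R-peak amplitude modulation.

    Returns (breathing rate in breaths/min from the spectral maximum in
    0.08-0.5 Hz, standard deviation in mV of the detrended respiration
    waveform); NaN when fewer than 30 R peaks or under 60 s of signal.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if len(rpeaks) < 30 or len(signal) / fs < 60.0:
        return np.nan, np.nan
    amps = np.asarray(signal, dtype=float)[rpeaks]
    times = rpeaks / fs
    grid, y = _uniform_series(amps, times)
    if grid is None:
        return np.nan, np.nan
    # detrend: remove the best-fit line (slow gain drift)
    coeffs = np.polyfit(grid, y, 1)
    y = y - np.polyval(coeffs, grid)
    sd = float(np.std(y, ddof=1))
    # single-segment Welch with heavy zero-padding for fine peak location
    nfft = int(2 ** np.ceil(np.log2(8 * len(y))))
    f, pxx = welch(y, fs=EDR_FS, nperseg=len(y), nfft=nfft)
    band = (f >= 0.08) & (f <= 0.5)
    if not band.any() or np.max(pxx[band]) <= 0:
        return np.nan, sd
    rate = float(60.0 * f[band][np.argmax(pxx[band])])
    return rate, sd


# ---------------------------------------------------------------- short range

def sr_beat_features(
    signal: np.ndarray, fs: float, fiducials: pd.DataFrame, rpeaks: np.ndarray
) -> pd.DataFrame:
    """Per-beat SR rows: wave amplitudes against the local baseline (median
    of the quiet segment preceding the beat), intervals in ms, RR and heart
    rate from neighbouring R peaks.  Absent fiducials give NaN fields."""
    x = np.asarray(signal, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    ms = 1000.0 / fs
    rows = []
    for bi in range(len(fiducials)):
        f = fiducials.iloc[bi]
        row = {}
        r = f["R"]
        blo = int(r - 0.300 * fs)
        bhi = int(r - 0.220 * fs)
        baseline = float(np.median(x[max(0, blo) : max(1, bhi)])) if bhi > 0 else np.nan

        def amp(fid):
            # 3-sample local mean suppresses the positive bias of picking
            # the peak sample as a max over noisy values
            v = f[fid]
            if np.isfinite(v) and np.isfinite(baseline):
                i = int(v)
                lo, hi = max(0, i - 1), min(len(x), i + 2)
                return float(np.mean(x[lo:hi])) - baseline
            return np.nan

        row["SR_p_mV"] = amp("P_peak")
        row["SR_q_mV"] = amp("Q")
        row["SR_r_mV"] = amp("R")
        row["SR_s_mV"] = amp("S")
        row["SR_t_mV"] = amp("T_peak")

        def interval(a, b):
            va, vb = f[a], f[b]
            if np.isfinite(va) and np.isfinite(vb):
                return (vb - va) * ms
            return np.nan

        row["SR_PR"] = interval("P_onset", "R")
        row["SR_QRS"] = interval("Q", "S")
        row["SR_QT"] = interval("Q", "T_offset")
        row["SR_P_duration"] = interval("P_onset", "P_offset")
        row["SR_T_duration"] = interval("T_onset", "T_offset")

        rr = np.nan
        if bi + 1 < len(rpeaks):
            rr = (rpeaks[bi + 1] - rpeaks[bi]) * ms
        elif bi > 0:
            rr = (rpeaks[bi] - rpeaks[bi - 1]) * ms
        row["SR_RR"] = rr
        row["SR_heart_rate"] = 60000.0 / rr if np.isfinite(rr) and rr > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=SR_FEATURES)


# ------------------------------------------------------------------- record

def record_feature_vector(
    record: EcgRecord,
    nn: NNSeries | None = None,
    fiducials: pd.DataFrame | None = None,
    rpeaks: np.ndarray | None = None,
) -> pd.Series:
    """Full named feature vector for one record; SR fields are means over
    beats where the field is present, HRV fields come from the NN series.
    Missing inputs propagate as NaN."""
    x = record.signal
    fs = record.fs
    if rpeaks is None:
        rpeaks = detect_r_peaks(x, fs)
    out = pd.Series(np.nan, index=FEATURE_COLUMNS, dtype=float)
    if len(rpeaks) >= 3 and nn is None:
        try:
            nn = build_nn_series(rpeaks, fs)
        except Exception:
            nn = None
    if nn is not None and len(nn) >= 2:
        td = time_domain_hrv(nn)
        out["HRV_SDNN"] = td["SDNN"]
        out["HRV_RMSSD"] = td["RMSSD"]
        out["HRV_pNN20"] = td["pNN20"]
        out["HRV_pNN50"] = td["pNN50"]
        out["HRV_MCVNN"] = td["MCVNN"]
        out["HRV_SDANN1"] = sdann_index(nn, 1.0)
        out["HRV_SDANN5"] = sdann_index(nn, 5.0)
        out["HRV_PAS"] = fragmentation_pas(nn)
        out["HRV_alpha1"], out["HRV_alpha2"] = dfa_alpha(nn)
        out["HRV_alpha1_mean"], out["HRV_alpha1_fluctuation"] = mfdfa_summary(nn)
        out["HRV_LF"], out["HRV_HF"] = frequency_domain(nn)
    if len(rpeaks) >= 1:
        out["breathing_rate"], out["breathing_signal_sd"] = edr_breathing(x, rpeaks, fs)
        if fiducials is None:
            fiducials = delineate_beats(x, fs, rpeaks)
        sr = sr_beat_features(x, fs, fiducials, rpeaks)
        for col in SR_FEATURES:
            vals = sr[col].dropna()
            if len(vals):
                out[col] = float(vals.mean())
    return out


def extract_feature_matrix(records: list) -> pd.DataFrame:
    """One feature row per record, indexed by subject_id, with an
    ``age_group`` column appended."""
    rows, idx, groups = [], [], []
    for rec in records:
        rows.append(record_feature_vector(rec))
        idx.append(rec.subject_id)
        groups.append(rec.age_group)
    df = pd.DataFrame(rows, index=pd.Index(idx, name="subject_id"))
    df["age_group"] = groups
    return df
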