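"""Explainability procedures for both classifiers.

Tree model: per-class additive feature attributions with TreeSHAP
semantics (base value plus per-feature contributions equals the model's
margin output), summarised per age group as a top-k ranking by mean
absolute attribution with a value-direction sign.

Raw-signal model: per-timestep saliency (absolute input gradient of the
target-class pre-softmax score), aligned on detected R peaks, averaged
within subject and then — each subject counting once — across the
subjects of each age group; the k highest mean-saliency timesteps are
marked and assigned to beat segments (P onset/offset, Q, R, S, T, TP),
yielding the segment-occupancy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import spearmanr

from .beats import delineate_beats, detect_r_peaks
from .models.feature_model import FeatureAgeClassifier

DEFAULT_WINDOW_BEFORE_MS = 300.0
DEFAULT_WINDOW_AFTER_MS = 500.0
#: half-width of the assignment band around the Q/R/S point fiducials
QRS_BAND_MS = 20.0
SEGMENT_NAMES = ("P_onset", "P_offset", "Q", "R", "S", "T", "TP")


@dataclass
class FeatureAttribution:
    """Per-record, per-class, per-feature additive attributions."""

    values: np.ndarray  # (n_records, n_classes, n_features)
    base_values: np.ndarray  # (n_records, n_classes)
    feature_names: list
    classes: np.ndarray


@dataclass
class AggregatedBeat:
    age_group: int
    waveform: np.ndarray
    saliency: np.ndarray
    n_subjects: int
    n_heartbeats: int
    marked: np.ndarray  # indices of the top-k mean-saliency timesteps


@dataclass
class SegmentOccupancy:
    percentages: dict  # segment name -> % of all marks across groups
    unassigned_pct: float
    n_marks: int


# ------------------------------------------------------------------ tree SHAP

def tree_attributions(model: FeatureAgeClassifier, X: pd.DataFrame) -> FeatureAttribution:
    """Exact tree-path (TreeSHAP) attributions on the margin scale."""
    Xt = model._transform(X)
    booster = model.booster_model_.get_booster()
    dm = xgb.DMatrix(Xt)
    contribs = booster.predict(dm, pred_contribs=True)
    # multiclass shape: (n, n_classes, n_features + 1); last slot = base value
    if contribs.ndim == 2:
        contribs = contribs[:, None, :]
    values = contribs[:, :, :-1]
    base = contribs[:, :, -1]
    return FeatureAttribution(
        values=values,
        base_values=base,
        feature_names=list(model.feature_names_),
        classes=model.classes_,
    )


def rank_features_per_group(
    attr: FeatureAttribution,
    feature_values: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k features per age group by mean |attribution| for that group's
    class, with direction = sign of the Spearman correlation between the
    feature value and its attribution for that class.

    Returns a tidy frame (age_group, rank, feature, mean_abs_attr,
    direction).  A degenerate all-zero attribution tensor raises
    ``ValueError``.
    """
    if np.allclose(attr.values, 0.0):
        raise ValueError("attribution matrix is identically zero; ranking undefined")
    fv = feature_values[attr.feature_names].to_numpy(dtype=float)
    rows = []
    for ci, cls in enumerate(attr.classes):
        a = attr.values[:, ci, :]  # (n_records, n_features)
        mean_abs = np.abs(a).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")[:k]
        for rank, fi in enumerate(order):
            col = fv[:, fi]
            ok = np.isfinite(col) & np.isfinite(a[:, fi])
            if ok.sum() >= 3 and np.std(col[ok]) > 0 and np.std(a[ok, fi]) > 0:
                rho = spearmanr(col[ok], a[ok, fi]).statistic
                direction = float(np.sign(rho)) if np.isfinite(rho) else 0.0
            else:
                direction = 0.0
            rows.append(
                {
                    "age_group": cls,
                    "rank": rank,
                    "feature": attr.feature_names[fi],
                    "mean_abs_attr": float(mean_abs[fi]),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- saliency

def crop_saliency(model, crop: np.ndarray, target_class) -> np.ndarray:
    """Per-timestep nonnegative relevance: |d score(target) / d input|."""
    crop = np.asarray(crop, dtype=float)
    single = crop.ndim == 1
    batch = crop[None, :] if single else crop
    grads = np.abs(model.input_gradient(batch, target_class))
    return grads[0] if single else grads


def beat_align_saliency(
    crops: list,
    saliencies: list,
    rpeaks_per_crop: list,
    fs: float,
    window_before_ms: float = DEFAULT_WINDOW_BEFORE_MS,
    window_after_ms: float = DEFAULT_WINDOW_AFTER_MS,
) -> tuple:
    """Average waveform and saliency over all beats of one subject, aligned
    on the R peak over [R - before, R + after).  Beats whose window exceeds
    crop bounds are skipped.  Returns (mean_beat, mean_saliency, n_beats);
    (None, None, 0) when no beat is usable."""
    before = int(round(window_before_ms / 1000.0 * fs))
    after = int(round(window_after_ms / 1000.0 * fs))
    if before + after < 2:
        raise ValueError("alignment window must cover at least 2 samples")
    beat_sum = np.zeros(before + after)
    sal_sum = np.zeros(before + after)
    n_beats = 0
    for crop, sal, rpeaks in zip(crops, saliencies, rpeaks_per_crop):
        crop = np.asarray(crop, dtype=float)
        sal = np.asarray(sal, dtype=float)
        for r in np.asarray(rpeaks, dtype=int):
            lo, hi = r - before, r + after
            if lo < 0 or hi > len(crop):
                continue
            beat_sum += crop[lo:hi]
            sal_sum += sal[lo:hi]
            n_beats += 1
    if n_beats == 0:
        return None, None, 0
    return beat_sum / n_beats, sal_sum / n_beats, n_beats


def aggregate_group_and_mark(
    subject_beats: dict,
    labels: dict,
    k: int = 8,
) -> dict:
    """Unweighted mean over subjects per age group, with the k highest
    mean-saliency timesteps marked (ties broken toward earlier indices).

    ``subject_beats`` maps subject_id -> (mean_beat, mean_saliency,
    n_beats); ``labels`` maps subject_id -> age group.  Groups with no
    usable subject are omitted with a warning.
    """
    by_group: dict = {}
    for sid, (beat, sal, n_beats) in subject_beats.items():
        if beat is None or n_beats == 0:
            warnings.warn(f"subject {sid}: no usable beats; skipped")
            continue
        by_group.setdefault(labels[sid], []).append((beat, sal, n_beats))
    out = {}
    for g in sorted(by_group):
        entries = by_group[g]
        beats = np.array([e[0] for e in entries])
        sals = np.array([e[1] for e in entries])
        mean_beat = beats.mean(axis=0)
        mean_sal = sals.mean(axis=0)
        # stable top-k with earlier-index tie-break
        order = np.lexsort((np.arange(len(mean_sal)), -mean_sal))
        marked = np.sort(order[:k])
        out[g] = AggregatedBeat(
            age_group=g,
            waveform=mean_beat,
            saliency=mean_sal,
            n_subjects=len(entries),
            n_heartbeats=int(sum(e[2] for e in entries)),
            marked=marked,
        )
    return out


# ------------------------------------------------------------ segment table

def delineate_aggregated_beat(
    waveform: np.ndarray, fs: float, window_before_ms: float = DEFAULT_WINDOW_BEFORE_MS
) -> dict:
    """Fiducial sample indices of an aggregated mean beat whose R peak sits
    ``window_before_ms`` into the window."""
    r_index = int(round(window_before_ms / 1000.0 * fs))
    fid = delineate_beats(waveform, fs, np.array([r_index])).iloc[0]
    return {name: (float(fid[name]) if np.isfinite(fid[name]) else np.nan) for name in fid.index}


def segment_occupancy(
    aggregated: dict,
    fiducials_per_group: dict | None = None,
    fs: float = 100.0,
    qrs_band_ms: float = QRS_BAND_MS,
    window_before_ms: float = DEFAULT_WINDOW_BEFORE_MS,
) -> SegmentOccupancy:
    """Assign every marked timestep to a beat segment and report percentages
    with the pooled denominator (total marks across all age groups).

    Segments: P_onset [P_onset, P_peak), P_offset [P_peak, P_offset],
    Q/R/S = fiducial ± ``qrs_band_ms``, T [T_onset, T_offset], TP outside
    [P_onset, T_offset].  Marks that cannot be assigned because a needed
    fiducial is missing count as unassigned.
    """
    band = qrs_band_ms / 1000.0 * fs
    counts = {name: 0 for name in SEGMENT_NAMES}
    unassigned = 0
    total = 0
    for g, agg in aggregated.items():
        if fiducials_per_group is not None and g in fiducials_per_group:
            fid = fiducials_per_group[g]
        else:
            fid = delineate_aggregated_beat(agg.waveform, fs, window_before_ms)
        for m in agg.marked:
            total += 1
            seg = _assign_segment(float(m), fid, band)
            if seg is None:
                unassigned += 1
            else:
                counts[seg] += 1
    if total == 0:
        raise ValueError("no marked timesteps to assign")
    pct = {name: 100.0 * c / total for name, c in counts.items()}
    return SegmentOccupancy(
        percentages=pct, unassigned_pct=100.0 * unassigned / total, n_marks=total
    )


def _assign_segment(m: float, fid: dict, band: float):
    def has(*names):
        return all(np.isfinite(fid.get(n, np.nan)) for n in names)

    # point fiducials first: they are point events widened to a band
    for name in ("Q", "R", "S"):
        if has(name) and abs(m - fid[name]) <= band:
            return name
    if has("P_onset", "P_peak") and fid["P_onset"] <= m < fid["P_peak"]:
        return "P_onset"
    if has("P_peak", "P_offset") and fid["P_peak"] <= m <= fid["P_offset"]:
        return "P_offset"
    if has("T_onset", "T_offset") and fid["T_onset"] <= m <= fid["T_offset"]:
        return "T"
    # TP: after the T offset, or ahead of the P onset (previous beat's tail)
    if has("T_offset") and m > fid["T_offset"]:
        return "TP"
    if has("P_onset") and m < fid["P_onset"]:
        return "TP"
    if not has("P_onset") and not has("T_offset"):
        return None
    return None
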