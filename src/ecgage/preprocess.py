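"""Cleaning, resampling, cropping, subject splitting and rebalancing.

The preparation protocol: keep a single lead, drop missing samples without
excluding the record, resample to 100 Hz with an anti-aliased polyphase
filter, tile the record into non-overlapping 3-second crops, split subjects
60/20/20 stratified by age group, and optionally oversample minority
classes to the majority count.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .records import Crop, EcgRecord

DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)
PARTITIONS = ("train", "validation", "test")


class RecordRejectedError(ValueError):
    pass


class StratificationError(ValueError):
    pass


def clean_and_resample(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Drop missing samples, then resample to ``target_fs``.

    Missing values (NaN) are removed and the remaining samples concatenated;
    their count and positions are recorded so crops can avoid straddling
    gaps wider than one sample.  Rejects records with more than 50 % missing.
    """
    x = np.asarray(record.signal, dtype=float)
    missing = ~np.isfinite(x)
    n_missing = int(missing.sum())
    if n_missing > 0.5 * len(x):
        raise RecordRejectedError(
            f"{record.subject_id}: {n_missing}/{len(x)} samples missing"
        )
    gaps = []
    if n_missing:
        # gap position = index in the cleaned signal where samples were dropped
        idx = np.flatnonzero(missing)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        removed_before = 0
        for run in runs:
            gaps.append((int(run[0]) - removed_before, len(run)))
            removed_before += len(run)
        x = x[~missing]

    ratio = Fraction(target_fs / record.fs).limit_denominator(10000)
    if ratio != 1:
        y = resample_poly(x, ratio.numerator, ratio.denominator)
    else:
        y = x
    scale = target_fs / record.fs
    gaps = [(int(round(pos * scale)), n) for pos, n in gaps]
    return EcgRecord(
        subject_id=record.subject_id,
        fs=float(target_fs),
        signal=y,
        age_group=record.age_group,
        n_missing_removed=n_missing,
        gaps=gaps,
        truth=record.truth,
    )


def split_subjects(
    records: list,
    fractions: tuple = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> dict:
    """Subject-level stratified split; returns subject_id -> partition.

    Every age group contributes at least one subject to each partition;
    groups with fewer than 3 subjects make that impossible and raise
    ``StratificationError``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    by_group: dict = {}
    for r in records:
        by_group.setdefault(r.age_group, []).append(r.subject_id)
    split = {}
    for g in sorted(by_group):
        ids = sorted(set(by_group[g]))
        if len(ids) < 3:
            raise StratificationError(
                f"age group {g} has {len(ids)} subjects; need >= 3 for stratification"
            )
        rng.shuffle(ids)
        n = len(ids)
        n_val = max(1, int(round(fractions[1] * n)))
        n_test = max(1, int(round(fractions[2] * n)))
        while n - n_val - n_test < 1:  # keep at least one training subject
            if n_val >= n_test and n_val > 1:
                n_val -= 1
            elif n_test > 1:
                n_test -= 1
            else:
                break
        for sid in ids[: n - n_val - n_test]:
            split[sid] = "train"
        for sid in ids[n - n_val - n_test : n - n_test]:
            split[sid] = "validation"
        for sid in ids[n - n_test :]:
            split[sid] = "test"
    return split


def tile_crops(record: EcgRecord, crop_s: float = 3.0) -> list:
    """Non-overlapping consecutive crops from sample 0; the trailing partial
    tile is discarded and crops straddling a cleaning gap wider than one
    sample are dropped."""
    crop_len = int(round(crop_s * record.fs))
    if len(record.signal) < crop_len:
        return []
    wide_gaps = [pos for pos, n in record.gaps if n > 1]
    crops = []
    for k in range(len(record.signal) // crop_len):
        start = k * crop_len
        if any(start < pos < start + crop_len for pos in wide_gaps):
            continue
        crops.append(
            Crop(
                subject_id=record.subject_id,
                start=start,
                samples=record.signal[start : start + crop_len],
                age_group=record.age_group,
            )
        )
    return crops


def random_oversample(items: list, labels: list, seed: int = 0) -> tuple:
    """Duplicate minority-class items (uniformly with replacement) until every
    class matches the majority count."""
    labels = list(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class must have at least one item")
    majority = max(len(v) for v in by_class.values())
    out_idx = list(range(len(items)))
    for lab in sorted(by_class, key=str):
        idx = by_class[lab]
        deficit = majority - len(idx)
        if deficit > 0:
            out_idx.extend(rng.choice(idx, size=deficit, replace=True).tolist())
    return [items[i] for i in out_idx], [labels[i] for i in out_idx]
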