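"""Age-group binning for the healthy-aging ECG cohort.

The cohort uses 15 ordinal age groups: 18-19, then thirteen consecutive
5-year bins from 20 to 84, and a final 85-92 bin.  A coarser 4-category
partition (18-34 / 35-49 / 50-64 / 65-92) is used when comparing against
feature-based classifiers that operate on broad categories.
"""

from __future__ import annotations

N_AGE_GROUPS = 15

#: inclusive [low, high] age bounds per ordinal group index
AGE_GROUP_BOUNDS: list[tuple[int, int]] = (
    [(18, 19)] + [(20 + 5 * i, 24 + 5 * i) for i in range(13)] + [(85, 92)]
)

#: contiguous partition of the 15 bins into 4 broad categories,
#: as (first_group, last_group) inclusive index ranges
DEFAULT_CONSOLIDATION: tuple[tuple[int, int], ...] = ((0, 3), (4, 6), (7, 9), (10, 14))


def group_label(index: int) -> str:
    """Human-readable label such as ``"25-29"`` for a group index."""
    low, high = AGE_GROUP_BOUNDS[index]
    return f"{low}-{high}"


def age_to_group(age: float) -> int:
    """Map an age in years to its ordinal group index (0-14)."""
    for i, (low, high) in enumerate(AGE_GROUP_BOUNDS):
        if low <= age <= high:
            return i
    raise ValueError(f"age {age} outside the supported range 18-92")


def consolidation_map(
    partition: tuple[tuple[int, int], ...] = DEFAULT_CONSOLIDATION,
) -> list[int]:
    """Return a length-15 list mapping each fine group to its broad category.

    ``partition`` must be contiguous, non-overlapping and cover all 15 bins.
    """
    mapping = [-1] * N_AGE_GROUPS
    for cat, (lo, hi) in enumerate(partition):
        if lo > hi:
            raise ValueError("empty category in consolidation partition")
        for g in range(lo, hi + 1):
            if mapping[g] != -1:
                raise ValueError("overlapping consolidation partition")
            mapping[g] = cat
    if any(m == -1 for m in mapping):
        raise ValueError("consolidation partition does not cover all 15 groups")
    expected = list(range(len(partition)))
    seen = sorted(set(mapping))
    if seen != expected or mapping != sorted(mapping):
        raise ValueError("consolidation partition must be contiguous and ordered")
    return mapping
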