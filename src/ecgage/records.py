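"""Core record containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EcgRecord:
    """One subject's single-lead ECG.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    fs : float
        Sampling rate in Hz.
    signal : np.ndarray
        Single-lead waveform in mV.
    age_group : int
        Ordinal age-group index (0-14).
    n_missing_removed : int
        Number of missing samples dropped during cleaning.
    gaps : list[tuple[int, int]]
        ``(index_in_cleaned_signal, n_dropped)`` positions where missing
        samples were removed; crops must not straddle gaps wider than one
        sample.
    truth : dict | None
        Generator ground truth (R-peak samples, fiducials, NN series).
        Present only on synthetic records and read only by tests and
        benchmarks — never by the analysis pipeline itself.
    """

    subject_id: str
    fs: float
    signal: np.ndarray
    age_group: int
    n_missing_removed: int = 0
    gaps: list = field(default_factory=list)
    truth: dict | None = None

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass
class Crop:
    """A fixed-length excerpt of one subject's record (half-open window)."""

    subject_id: str
    start: int
    samples: np.ndarray
    age_group: int
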