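"""Minimal WFDB-compatible record I/O and label sidecar handling.

Writes and reads the classic header (`.hea`) plus signal (`.dat`) layout
using format 16 (little-endian 16-bit integers) with an explicit gain and
baseline per channel.  This covers round-tripping the synthetic cohorts
and reading simple format-16 lead sets; exotic WFDB storage formats are
out of scope.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .records import EcgRecord

_FMT = 16
_ADC_GAIN = 1000.0  # ADC units per mV
_ADC_BASELINE = 0


class LeadNotFoundError(KeyError):
    pass


def write_wfdb_record(record: EcgRecord, directory: str, lead_name: str = "II") -> str:
    """Write ``record`` as ``<subject_id>.hea`` + ``<subject_id>.dat``."""
    os.makedirs(directory, exist_ok=True)
    name = record.subject_id
    digital = np.round(record.signal * _ADC_GAIN + _ADC_BASELINE)
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(os.path.join(directory, name + ".dat"), "wb") as f:
        f.write(digital.tobytes())
    fs = int(record.fs) if float(record.fs).is_integer() else record.fs
    lines = [
        f"{name} 1 {fs} {len(digital)}",
        f"{name}.dat {_FMT} {_ADC_GAIN:g}({_ADC_BASELINE})/mV 16 0 0 0 0 {lead_name}",
    ]
    with open(os.path.join(directory, name + ".hea"), "w") as f:
        f.write("\n".join(lines) + "\n")
    return os.path.join(directory, name)


def read_wfdb_record(path: str, lead_name: str = "II", age_group: int = -1) -> EcgRecord:
    """Read a format-16 WFDB record and return the requested lead in mV.

    ``path`` is the record path without extension.  Raises
    ``LeadNotFoundError`` if the lead is absent and ``ValueError`` on a
    malformed header.
    """
    hea = path + ".hea"
    with open(hea) as f:
        lines = [ln.strip() for ln in f if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed WFDB header line: {lines[0]!r}")
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except ValueError as e:
        raise ValueError(f"malformed WFDB header line: {lines[0]!r}") from e
    sig_lines = lines[1 : 1 + n_sig]
    leads, gains, baselines, fmts, files = [], [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        if len(parts) < 3:
            raise ValueError(f"malformed WFDB signal line: {ln!r}")
        files.append(parts[0])
        fmts.append(int(parts[1].split("x")[0]))
        gain_spec = parts[2]
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(float(b.rstrip(")")))
        else:
            gains.append(float(gain_part) if gain_part else 200.0)
            baselines.append(0.0)
        leads.append(parts[-1])
    if lead_name not in leads:
        raise LeadNotFoundError(f"lead {lead_name!r} not in record (has {leads})")
    idx = leads.index(lead_name)
    if any(f != _FMT for f in fmts):
        raise ValueError(f"unsupported WFDB signal format(s) {fmts}; only 16 supported")
    dat = os.path.join(os.path.dirname(path), files[idx])
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        # single multiplexed .dat file when all channels share it
        if len(set(files)) == 1:
            raw = raw.reshape(-1, n_sig)[:, idx]
    raw = raw[:n_samp] if n_samp > 0 else raw
    signal = (raw.astype(float) - baselines[idx]) / gains[idx]
    return EcgRecord(
        subject_id=os.path.basename(path),
        fs=fs,
        signal=signal,
        age_group=age_group,
    )


def write_label_table(records: list, path: str) -> None:
    """Sidecar CSV: subject_id, age_group, gender (placeholder, unused)."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age_group": [r.age_group for r in records],
            "gender": ["NA"] * len(records),
        }
    )
    df.to_csv(path, index=False)


def read_label_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if not {"subject_id", "age_group"} <= set(df.columns):
        raise ValueError("label table must have subject_id and age_group columns")
    return df


def write_cohort(records: list, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for r in records:
        write_wfdb_record(r, directory)
    write_label_table(records, os.path.join(directory, "labels.csv"))


def read_cohort(directory: str, lead_name: str = "II") -> list:
    labels = read_label_table(os.path.join(directory, "labels.csv"))
    records = []
    for _, row in labels.iterrows():
        rec = read_wfdb_record(
            os.path.join(directory, row["subject_id"]),
            lead_name=lead_name,
            age_group=int(row["age_group"]),
        )
        records.append(rec)
    return records
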