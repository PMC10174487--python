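"""Reading, selecting and persisting EHG cohorts.

Real recordings come as WFDB-style record pairs: a text header (``.hea``)
describing the signal layout plus key-value comment lines carrying the
clinical fields, and a binary file (``.dat``) of 16-bit little-endian ADC
samples.  Physical units are restored with the per-channel gain/baseline
from the header.  Only the first abdominal channel (``s1``) is used.

Cohort selection applies the study inclusion rules: recordings made
strictly after 26 completed weeks of gestation, one (the latest) record
per mother, and every signal standardised to exactly 30 minutes at its
native sampling rate by zero-padding or truncation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Completed-week threshold for preterm birth (37 weeks).
PRETERM_THRESHOLD_DAYS = 259

#: Inclusion threshold: recordings strictly after 26 completed weeks.
MIN_RECORDING_DAYS = 26 * 7

#: Standardised recording duration in seconds.
STANDARD_DURATION_S = 1800.0

_SCHEMA_TAG = "ehgterm-cohort-v1"

BINARY_FIELDS = (
    "parous",
    "prev_abortions",
    "hypertension",
    "diabetes",
    "placental_position",
    "bleeding_t1",
    "bleeding_t2",
    "funneling",
    "smoker",
)


class DataIOError(Exception):
    """Base class for cohort I/O failures."""


class MissingFileError(DataIOError):
    pass


class UnknownChannelError(DataIOError):
    pass


class HeaderParseError(DataIOError):
    pass


class SchemaError(DataIOError):
    pass


class DegenerateCohortError(ValueError):
    """Raised when a requested cohort cannot contain both outcome classes."""


@dataclass
class EhgRecording:
    """One mother's raw single-channel EHG trace.

    Amplitudes are physical units (microvolt).  ``source`` tags the
    originating database or marks the record as synthetic.
    """

    record_id: str
    mother_id: str
    fs: float
    samples: np.ndarray
    channel_name: str = "s1"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ClinicalRecord:
    """Clinical covariates for one mother; ``None`` marks a missing entry.

    ``label`` is derived from the gestational age at delivery: preterm
    iff delivery happened before 259 days (37 completed weeks).
    """

    age: float | None
    ga_recording_days: float
    weight_kg: float | None
    parous: bool | None
    prev_abortions: bool | None
    hypertension: bool | None
    diabetes: bool | None
    placental_position: bool | None
    bleeding_t1: bool | None
    bleeding_t2: bool | None
    funneling: bool | None
    smoker: bool | None
    ga_delivery_days: float

    def __post_init__(self) -> None:
        if self.ga_recording_days >= self.ga_delivery_days:
            raise ValueError("recording must precede delivery")

    @property
    def label(self) -> str:
        return "preterm" if self.ga_delivery_days < PRETERM_THRESHOLD_DAYS else "term"

    @property
    def is_preterm(self) -> bool:
        return self.label == "preterm"


@dataclass
class CohortTable:
    """Aligned (signal, clinical) rows; at most one row per mother."""

    rows: list[tuple[EhgRecording, ClinicalRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rec.mother_id for rec, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("cohort contains duplicate mother_ids")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> np.ndarray:
        """Binary outcome vector, 1 = preterm."""
        return np.array([int(cl.is_preterm) for _, cl in self.rows])

    @property
    def signals(self) -> list[EhgRecording]:
        return [rec for rec, _ in self.rows]

    @property
    def clinical(self) -> list[ClinicalRecord]:
        return [cl for _, cl in self.rows]

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical table as a DataFrame (``NaN``/``NA`` marks missing)."""
        recs = []
        for rec, cl in self.rows:
            row: dict[str, object] = {
                "mother_id": rec.mother_id,
                "record_id": rec.record_id,
                "age": cl.age,
                "ga_recording_days": cl.ga_recording_days,
                "weight_kg": cl.weight_kg,
                "ga_delivery_days": cl.ga_delivery_days,
                "label": cl.label,
            }
            for name in BINARY_FIELDS:
                val = getattr(cl, name)
                row[name] = pd.NA if val is None else bool(val)
            recs.append(row)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Gestational-age notation
# ---------------------------------------------------------------------------

def parse_gestation(text: str) -> float:
    """Convert ``"weeks/days"`` (or plain days/decimal weeks) to days.

    ``"31/0"`` -> 217; ``"30/4"`` -> 214.  A bare number below 50 is read
    as decimal weeks, otherwise as days.
    """
    text = text.strip()
    if "/" in text:
        weeks_s, days_s = text.split("/", 1)
        return 7 * int(weeks_s) + int(days_s)
    value = float(text)
    return value * 7 if value < 50 else value


# ---------------------------------------------------------------------------
# WFDB-compatible record I/O
# ---------------------------------------------------------------------------

_CLINICAL_KEYS = {
    "age": "age",
    "weight": "weight_kg",
    "gestation_at_recording": "ga_recording_days",
    "gestation_at_delivery": "ga_delivery_days",
    "parous": "parous",
    "previous_abortions": "prev_abortions",
    "hypertension": "hypertension",
    "diabetes": "diabetes",
    "placental_position": "placental_position",
    "bleeding_first_trimester": "bleeding_t1",
    "bleeding_second_trimester": "bleeding_t2",
    "funneling": "funneling",
    "smoker": "smoker",
}


def _parse_bool(text: str) -> bool | None:
    t = text.strip().lower()
    if t in {"", "none", "na", "n/a"}:
        return None
    if t in {"yes", "true", "1", "front"}:
        return True
    if t in {"no", "false", "0", "end"}:
        return False
    raise HeaderParseError(f"cannot interpret {text!r} as a binary clinical value")


def read_wfdb_record(path: str | os.PathLike) -> tuple[EhgRecording, ClinicalRecord]:
    """Read a WFDB-style header/signal pair and its clinical comments.

    ``path`` is the record path without extension; ``path.hea`` and the
    signal file it references must exist.  Samples are returned in
    physical units, ``(adc - baseline) / gain``, for channel ``s1`` only.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise MissingFileError(f"header not found: {hea}")
    lines = [ln.rstrip("\n") for ln in hea.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    if len(head) < 4:
        raise HeaderParseError(f"malformed record line: {lines[0]!r}")
    record_id = head[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2])
        n_samples = int(head[3])
    except ValueError as exc:
        raise HeaderParseError(f"malformed record line: {lines[0]!r}") from exc

    signal_lines = lines[1 : 1 + n_sig]
    comments = [ln.lstrip("# ").strip() for ln in lines[1 + n_sig :] if ln.startswith("#")]

    channel_index = None
    sig_file = gain = baseline = None
    channel_names = []
    for idx, ln in enumerate(signal_lines):
        parts = ln.split()
        if len(parts) < 3:
            raise HeaderParseError(f"malformed signal line: {ln!r}")
        name = parts[-1]
        channel_names.append(name)
        if name == "s1":
            channel_index = idx
            sig_file = parts[0]
            if parts[1] != "16":
                raise HeaderParseError(f"unsupported sample format {parts[1]!r}")
            gain_field = parts[2]
            if "(" in gain_field:
                g, b = gain_field.split("(")
                gain = float(g)
                baseline = float(b.rstrip(")").split(")")[0])
            else:
                gain, baseline = float(gain_field.split("/")[0]), 0.0
    if channel_index is None:
        raise UnknownChannelError(f"channel 's1' not found (channels: {channel_names})")

    dat = hea.parent / sig_file
    if not dat.exists():
        raise MissingFileError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise HeaderParseError(
            f"signal file holds {raw.size} samples, header declares {n_samples * n_sig}"
        )
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig)
    physical = (raw[:, channel_index].astype(float) - baseline) / gain

    fields: dict[str, object] = {key: None for key in _CLINICAL_KEYS.values()}
    for comment in comments:
        if not comment:
            continue
        key, _, value = comment.partition(" ")
        key = key.strip().lower()
        if key not in _CLINICAL_KEYS:
            continue
        target = _CLINICAL_KEYS[key]
        value = value.strip()
        if value.lower() in {"", "none", "na", "n/a"}:
            fields[target] = None
        elif target in {"ga_recording_days", "ga_delivery_days"}:
            fields[target] = parse_gestation(value)
        elif target in {"age", "weight_kg"}:
            fields[target] = float(value)
        else:
            fields[target] = _parse_bool(value)
    if fields["ga_recording_days"] is None or fields["ga_delivery_days"] is None:
        raise HeaderParseError("header lacks gestational ages at recording/delivery")

    recording = EhgRecording(
        record_id=record_id,
        mother_id=record_id,
        fs=fs,
        samples=physical,
        channel_name="s1",
        source="TPEHG_DB",
    )
    clinical = ClinicalRecord(**fields)  # type: ignore[arg-type]
    return recording, clinical


def write_wfdb_record(
    path: str | os.PathLike,
    recording: EhgRecording,
    clinical: ClinicalRecord,
    gain: float = 100.0,
) -> None:
    """Write a record as a WFDB-compatible header + 16-bit signal pair."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    adc = np.clip(np.round(recording.samples * gain), -32768, 32767).astype("<i2")
    dat_name = base.name + ".dat"
    (base.parent / dat_name).write_bytes(adc.tobytes())
    lines = [
        f"{base.name} 1 {recording.fs:g} {recording.samples.size}",
        f"{dat_name} 16 {gain:g}(0)/uV 16 0 {int(adc[0])} 0 0 s1",
    ]

    def fmt(value: object) -> str:
        return "None" if value is None else str(value)

    rev = {v: k for k, v in _CLINICAL_KEYS.items()}
    for attr in rev:
        value = getattr(clinical, attr)
        if attr in {"ga_recording_days", "ga_delivery_days"}:
            weeks, days = divmod(int(round(value)), 7)
            value = f"{weeks}/{days}"
        lines.append(f"#{rev[attr].capitalize()} {fmt(value)}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------

def standardize_duration(
    recording: EhgRecording, duration_s: float = STANDARD_DURATION_S
) -> EhgRecording:
    """Pad with trailing zeros or truncate to exactly ``duration_s``."""
    target = int(round(duration_s * recording.fs))
    samples = recording.samples
    if samples.size > target:
        samples = samples[:target]
    elif samples.size < target:
        samples = np.concatenate([samples, np.zeros(target - samples.size)])
    return replace(recording, samples=samples)


def select_cohort(
    records: Sequence[tuple[EhgRecording, ClinicalRecord]],
    duration_s: float = STANDARD_DURATION_S,
) -> CohortTable:
    """Apply the inclusion rules and standardise signal durations.

    Records at or before 26 completed weeks (182 days) are dropped; for
    mothers with several qualifying records only the latest is kept.
    The operation is idempotent.
    """
    best: dict[str, tuple[EhgRecording, ClinicalRecord]] = {}
    for rec, cl in records:
        if cl.ga_recording_days <= MIN_RECORDING_DAYS:
            continue
        prev = best.get(rec.mother_id)
        if prev is None or cl.ga_recording_days > prev[1].ga_recording_days:
            best[rec.mother_id] = (rec, cl)
    rows = [
        (standardize_duration(rec, duration_s), cl)
        for rec, cl in sorted(best.values(), key=lambda rc: rc[0].mother_id)
    ]
    return CohortTable(rows=rows)


# ---------------------------------------------------------------------------
# Internal cohort container
# ---------------------------------------------------------------------------

def save_cohort(cohort: CohortTable, path: str | os.PathLike) -> None:
    """Persist a cohort: clinical CSV (empty cell = missing) + signal array file."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    frame = cohort.clinical_frame()
    frame.to_csv(base / "clinical.csv", index=False, na_rep="")
    arrays = {
        f"signal_{i}": rec.samples for i, rec in enumerate(cohort.signals)
    }
    meta = pd.DataFrame(
        {
            "record_id": [r.record_id for r in cohort.signals],
            "mother_id": [r.mother_id for r in cohort.signals],
            "fs": [r.fs for r in cohort.signals],
            "channel_name": [r.channel_name for r in cohort.signals],
            "source": [r.source for r in cohort.signals],
        }
    )
    meta.to_csv(base / "signals_meta.csv", index=False)
    np.savez(base / "signals.npz", schema=np.array(_SCHEMA_TAG), **arrays)


def load_cohort(path: str | os.PathLike) -> CohortTable:
    base = Path(path)
    csv_path = base / "clinical.csv"
    npz_path = base / "signals.npz"
    if not csv_path.exists() or not npz_path.exists():
        raise MissingFileError(f"cohort container incomplete at {base}")
    frame = pd.read_csv(csv_path, keep_default_na=True)
    meta = pd.read_csv(base / "signals_meta.csv")
    with np.load(npz_path, allow_pickle=False) as npz:
        if "schema" not in npz or str(npz["schema"]) != _SCHEMA_TAG:
            raise SchemaError(f"unrecognised cohort container schema in {npz_path}")
        signals = [npz[f"signal_{i}"] for i in range(len(meta))]

    def cell(row: pd.Series, name: str) -> object:
        value = row[name]
        return None if pd.isna(value) else value

    rows = []
    for i, row in frame.iterrows():
        rec = EhgRecording(
            record_id=str(meta.loc[i, "record_id"]),
            mother_id=str(meta.loc[i, "mother_id"]),
            fs=float(meta.loc[i, "fs"]),
            samples=signals[i],
            channel_name=str(meta.loc[i, "channel_name"]),
            source=str(meta.loc[i, "source"]),
        )
        kwargs: dict[str, object] = {
            "age": cell(row, "age"),
            "weight_kg": cell(row, "weight_kg"),
            "ga_recording_days": float(row["ga_recording_days"]),
            "ga_delivery_days": float(row["ga_delivery_days"]),
        }
        for name in BINARY_FIELDS:
            value = cell(row, name)
            kwargs[name] = None if value is None else bool(value)
        rows.append((rec, ClinicalRecord(**kwargs)))  # type: ignore[arg-type]
    return CohortTable(rows=rows)
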