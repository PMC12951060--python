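"""Plain-text I/O: waveform CSVs, cohort metadata, feature tables, model JSON.

All formats are line-oriented text.  Waveform files are two-column CSV
(time_s, amplitude) with a single ``#``-prefixed header line carrying the
subject id, hand and sampling rate.  Numeric round-tripping is byte-stable at
12 significant digits.

Column-name mapping for feature tables (Greek symbols are not portable in CSV
headers): a signed difference ΔC9CV becomes ``dC9CV``; an absolute difference
|ΔC10| becomes ``absdC10``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pulseharm.errors import WaveformParseError

SYNTAX_THRESHOLD = 22.0
FLOAT_FORMAT = "%.12g"
#: feature tables feed model selection, where near-tie AIC comparisons demand
#: an exact float64 round-trip; 17 significant digits guarantee it
FEATURE_FLOAT_FORMAT = "%.17g"
MODEL_SCHEMA_VERSION = 1


@dataclass
class WaveformRecord:
    """One hand's raw PPG sample series (arbitrary units) with sampling rate."""

    subject_id: str
    hand: str  # "left" | "right"
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2 * self.sampling_rate:
            raise ValueError("record must cover at least 2 seconds")
        if np.any(~np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class SubjectRecord:
    """Per-subject metadata plus (optionally) the extracted feature vector."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float
    syntax_score: float
    features: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.syntax_score < 0:
            raise ValueError("syntax_score must be non-negative")

    @property
    def label(self) -> bool:
        """True when the SYNTAX score is at or above the severity threshold 22."""
        return self.syntax_score >= SYNTAX_THRESHOLD


def write_waveform(record: WaveformRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.samples.size) / record.sampling_rate
    header = (
        f"# subject_id={record.subject_id} hand={record.hand} "
        f"sampling_rate_hz={FLOAT_FORMAT % record.sampling_rate}\n"
        "time_s,amplitude\n"
    )
    body = "\n".join(
        f"{FLOAT_FORMAT % ti},{FLOAT_FORMAT % si}"
        for ti, si in zip(t, record.samples)
    )
    path.write_text(header + body + "\n")


def read_waveform(path: str | Path) -> WaveformRecord:
    """Parse a waveform CSV; errors carry the offending 1-based line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise WaveformParseError("missing '#' metadata header", line=1)
    meta = dict(
        item.split("=", 1) for item in lines[0].lstrip("# ").split() if "=" in item
    )
    for key in ("subject_id", "hand", "sampling_rate_hz"):
        if key not in meta:
            raise WaveformParseError(f"header missing {key}", line=1)
    fs = float(meta["sampling_rate_hz"])
    samples = []
    prev_t = -np.inf
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise WaveformParseError("expected two comma-separated columns", line=i)
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise WaveformParseError(f"unparseable number in {line!r}", line=i) from None
        if not np.isfinite(t) or t <= prev_t:
            raise WaveformParseError("time column not strictly increasing", line=i)
        if not np.isfinite(v):
            raise WaveformParseError("non-finite amplitude sample", line=i)
        prev_t = t
        samples.append(v)
    return WaveformRecord(
        subject_id=meta["subject_id"],
        hand=meta["hand"],
        sampling_rate=fs,
        samples=np.array(samples),
    )


def write_cohort(records: list[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "syntax_score": [r.syntax_score for r in records],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            sex=row.sex,
            age=float(row.age),
            syntax_score=float(row.syntax_score),
        )
        for row in df.itertuples()
    ]


def write_feature_table(records: list[SubjectRecord], path: str | Path) -> None:
    """One row per subject: id, sex, age, syntax_score, label, features."""
    missing = [r.subject_id for r in records if r.features is None]
    if missing:
        raise ValueError(f"records missing features: {missing}")
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "age": r.age,
            "syntax_score": r.syntax_score,
            "label": int(r.label),
        }
        row.update(r.features)
        rows.append(row)
    cols = ["subject_id", "sex", "age", "syntax_score", "label"]
    if records:
        cols += list(records[0].features.keys())
    pd.DataFrame(rows, columns=cols).to_csv(
        path, index=False, float_format=FEATURE_FLOAT_FORMAT
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Feature table as a DataFrame indexed by subject_id."""
    return pd.read_csv(path, index_col="subject_id", float_precision="round_trip")


def write_model_json(payload: dict, path: str | Path) -> None:
    payload = {"schema_version": MODEL_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {payload.get('schema_version')}")
    return payload
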