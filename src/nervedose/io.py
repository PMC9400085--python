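"""Waveform and table I/O with schema validation.

Waveforms travel as single-channel float32 WAV plus a JSON sidecar
carrying the protocol, tone annotations, seed and a config hash.
Tables are UTF-8 comma-delimited text with a mandatory header row and
'.' decimals.  ``validate_table`` checks a named schema (required
columns, types, value constraints) and pinpoints offending rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .nerve_signal import NerveTrace


class SchemaError(ValueError):
    """Raised when a table violates its declared schema."""


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_trace(trace: NerveTrace, wav_path, meta_path=None) -> tuple:
    """Write a trace as float32 WAV plus JSON sidecar; returns both paths."""
    wav_path = Path(wav_path)
    meta_path = Path(meta_path) if meta_path else wav_path.with_suffix(".json")
    wavfile.write(wav_path, int(round(trace.sampling_rate)),
                  trace.samples.astype(np.float32))
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "annotations": [[float(t), float(s)] for t, s in trace.annotations],
        "baseline_span": [float(trace.baseline_span[0]), float(trace.baseline_span[1])],
        "meta": trace.meta,
        "config_hash": config_hash(trace.meta.get("config", {})),
    }
    meta_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True, default=str))
    return wav_path, meta_path


def read_trace(wav_path, meta_path=None) -> NerveTrace:
    """Read a WAV + JSON sidecar pair back into a NerveTrace."""
    wav_path = Path(wav_path)
    meta_path = Path(meta_path) if meta_path else wav_path.with_suffix(".json")
    rate, samples = wavfile.read(wav_path)
    sidecar = json.loads(meta_path.read_text())
    return NerveTrace(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=float(sidecar.get("sampling_rate", rate)),
        annotations=tuple((float(t), float(s)) for t, s in sidecar["annotations"]),
        baseline_span=tuple(sidecar["baseline_span"]),
        meta=sidecar.get("meta", {}),
    )


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict           # column -> "numeric" | "string" | "integer"
    checks: tuple = ()      # (description, vectorised predicate) pairs


SCHEMAS = {
    "sigma": TableSchema(
        name="sigma",
        columns={"animal_id": "string", "treatment": "string", "day": "integer",
                 "spl_db": "numeric", "sigma": "numeric",
                 "n_reps_averaged": "integer"},
        checks=(
            ("sigma must be > 0", lambda df: df["sigma"] > 0),
            ("n_reps_averaged must be >= 1", lambda df: df["n_reps_averaged"] >= 1),
        ),
    ),
    "morphometry": TableSchema(
        name="morphometry",
        columns={"animal_id": "string", "treatment": "string", "day": "integer",
                 "neuron_count": "numeric", "organ_cell_count": "numeric",
                 "nerve_cells_per_100um": "numeric", "nerve_width_um": "numeric"},
        checks=(
            ("counts must be >= 0",
             lambda df: (df["neuron_count"] >= 0) & (df["organ_cell_count"] >= 0)
                        & (df["nerve_cells_per_100um"] >= 0)),
            ("nerve_width_um must be > 0", lambda df: df["nerve_width_um"] > 0),
        ),
    ),
    "displacement": TableSchema(
        name="displacement",
        columns={"animal_id": "string", "spl_db": "numeric",
                 "displacement_nm": "numeric"},
        checks=(
            ("displacement_nm must be > 0", lambda df: df["displacement_nm"] > 0),
        ),
    ),
}


def validate_table(table, schema: str) -> pd.DataFrame:
    """Validate a DataFrame or CSV path against a named schema.

    Raises SchemaError naming the missing columns, the mistyped columns,
    or the first offending rows of each violated value constraint.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    if isinstance(table, (str, Path)):
        # round_trip parsing: full-precision floats survive write -> read
        df = pd.read_csv(table, float_precision="round_trip")
    else:
        df = table.copy()

    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing columns {missing}")
    for col, kind in sch.columns.items():
        if kind in ("numeric", "integer") and not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"schema {schema!r}: column {col!r} must be numeric")
        if kind == "integer":
            vals = df[col].to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise SchemaError(f"schema {schema!r}: column {col!r} must be integer-valued")
    problems = []
    for desc, pred in sch.checks:
        ok = pred(df)
        if not bool(ok.all()):
            bad = df.index[~ok].tolist()[:10]
            problems.append(f"{desc} (rows {bad})")
    if problems:
        raise SchemaError(f"schema {schema!r} violated: " + "; ".join(problems))
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Comma-delimited UTF-8 with header; floats at full round-trip precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
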