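"""CSV/JSON readers and writers for the pipeline tables.

Interchange format is plain CSV with explicit headers.  Provenance (seed,
config hash, package version) is carried as ``# key=value`` comment lines
ahead of the header; readers skip them transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .synthetic import SAMPLE_COLUMNS, SURVEY_COLUMNS


class SchemaError(ValueError):
    """A table is missing required columns or holds malformed values."""


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a CSV with ``# key=value`` provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def read_table(path, required_columns: list[str], numeric_columns: list[str]) -> pd.DataFrame:
    """Read a provenance-commented CSV and validate its schema.

    Missing columns raise :class:`SchemaError` naming them; non-numeric
    values in numeric columns raise with 1-based data line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for col in numeric_columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # +1 header, +1 1-based
            raise SchemaError(f"{path.name}: non-numeric {col!r} at lines {lines}")
        frame[col] = coerced
    return frame


def read_samples(path) -> pd.DataFrame:
    """Read a soil-sample table (site, period, layer bounds, ECe, θ)."""
    numeric = ["site_id", "layer_top_cm", "layer_bottom_cm", "ece_dsm", "theta"]
    return read_table(path, SAMPLE_COLUMNS, numeric)


def read_survey(path) -> pd.DataFrame:
    """Read an EM38 survey table (coordinates, period, four channels)."""
    numeric = ["x_m", "y_m", "ec_h05", "ec_h10", "ec_v05", "ec_v10"]
    return read_table(path, SURVEY_COLUMNS, numeric)


def write_samples(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_table(frame, path, metadata)


def write_survey(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_table(frame, path, metadata)


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(obj)}")
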