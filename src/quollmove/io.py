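"""Readers and writers for telemetry, accelerometry and result tables.

All tables are RFC-4180 CSV handled through pandas.  Fix and
accelerometer timestamps are ISO-8601 and stored internally as UTC.
Coordinates must already be projected planar metres; longitude/latitude
inputs are rejected rather than silently re-projected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from io import StringIO

import numpy as np
import pandas as pd

from .config import StudyConfig

log = logging.getLogger("quollmove")

__all__ = [
    "FormatError",
    "ValidationError",
    "read_fixes",
    "write_fixes",
    "read_accel",
    "write_accel",
    "write_manifest",
]

FIX_COLUMNS = ["id", "timestamp", "x", "y", "hdop"]
ACCEL_COLUMNS = ["id", "timestamp", "ax", "ay", "az", "temperature"]


class FormatError(ValueError):
    """A file does not match its documented schema."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


def _parse_table(path, required, numeric):
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna()
    parsed = {"timestamp": ts}
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna()
        parsed[col] = vals
    bad |= df["id"].isna()
    for idx in np.flatnonzero(bad.to_numpy()):
        # +2: header line plus 1-based numbering
        log.warning("%s: rejected malformed row at line %d", path, idx + 2)
    out = pd.DataFrame({"individual_id": df["id"], **parsed})[~bad.to_numpy()]
    return out.reset_index(drop=True), int(bad.sum())


def _check_projected(df, path):
    # degrees-looking coordinates are almost surely lon/lat, not metres
    if len(df) and df["x"].abs().le(180).all() and df["y"].abs().le(90).all():
        raise ValidationError(
            f"{path}: coordinates look like lon/lat degrees; supply projected "
            "planar metres (e.g. UTM) — conversion is out of scope"
        )


def read_fixes(path, config: StudyConfig | None = None) -> pd.DataFrame:
    """Read a GPS fix table, grouped by individual and time-sorted.

    Expected columns: ``id, timestamp, x, y, hdop`` (extra columns such
    as ``temperature`` are carried through if numeric).  Malformed rows
    are logged with line numbers and dropped; duplicate timestamps
    within an individual raise :class:`ValidationError`.
    """
    df, n_rejected = _parse_table(path, FIX_COLUMNS, ["x", "y", "hdop"])
    if n_rejected:
        log.info("%s: %d malformed row(s) rejected", path, n_rejected)
    _check_projected(df, path)
    if (df["hdop"] < 0).any():
        raise ValidationError(f"{path}: negative hdop values")
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    dup = df.duplicated(["individual_id", "timestamp"])
    if dup.any():
        offenders = df.loc[dup, ["individual_id", "timestamp"]]
        raise ValidationError(
            f"{path}: duplicate timestamps per individual:\n{offenders.to_string(index=False)}"
        )
    df.attrs["n_rejected"] = n_rejected
    return df.reset_index(drop=True)


def write_fixes(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "id": df["individual_id"],
            "timestamp": df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "x": df["x"],
            "y": df["y"],
            "hdop": df["hdop"],
        }
    )
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_accel(path) -> pd.DataFrame:
    """Read a tri-axial accelerometer stream (5-s cadence, g units)."""
    df, _ = _parse_table(path, ACCEL_COLUMNS, ["ax", "ay", "az", "temperature"])
    for axis in ("ax", "ay", "az"):
        if (df[axis].abs() > 4.0 + 1e-9).any():
            raise ValidationError(f"{path}: |{axis}| exceeds the 4 g sensor range")
    return df.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_accel(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "id": df["individual_id"],
            "timestamp": df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "ax": df["ax"],
            "ay": df["ay"],
            "az": df["az"],
            "temperature": df["temperature"],
        }
    )
    out.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_manifest(path, *, command: str, seed, config: StudyConfig, inputs=(), outputs=()) -> None:
    """Write the JSON run manifest that makes every CLI run reconstructable."""
    manifest = {
        "command": command,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def fixes_from_csv_text(text: str, config: StudyConfig | None = None) -> pd.DataFrame:
    """Convenience for tests: parse a fix table from an in-memory string."""
    return read_fixes(StringIO(text), config)
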