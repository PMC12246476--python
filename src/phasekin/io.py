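"""Delimited-text I/O with schema validation.

One strict tabular dialect everywhere: comma-separated, header row,
UTF-8, "." decimal.  Lines starting with ``#`` are provenance headers
(package version, seed, config hash) and are skipped on read.  Volume
fractions are stored as plain fractions but "%"-suffixed cells
("0.017%") are accepted on input and converted.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "parse_fraction",
    "PROGRESS_CURVE_SCHEMA",
    "CALIBRATION_SCHEMA",
    "PHASE_COMPOSITION_SCHEMA",
    "RATIO_SCHEMA",
    "SNARF_CALIBRATION_SCHEMA",
    "SNARF_MEASUREMENT_SCHEMA",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def parse_fraction(value) -> float:
    """Parse a fraction that may be written with a '%' suffix.

    '0.017%' -> 1.7e-4; '0.00017' -> 1.7e-4.
    """
    if isinstance(value, str) and value.strip().endswith("%"):
        return float(value.strip().rstrip("%")) / 100.0
    return float(value)


@dataclass(frozen=True)
class TableSchema:
    """Required columns and their parsers for one table kind.

    ``columns`` maps column name -> parser (float, str, int or
    parse_fraction).  Extra columns in a file are tolerated and passed
    through untouched.
    """

    name: str
    columns: dict = field(default_factory=dict)


PROGRESS_CURVE_SCHEMA = TableSchema("progress_curves", {
    "replicate_id": str, "condition_label": str,
    "time_s": float, "signal": float,
})
CALIBRATION_SCHEMA = TableSchema("calibration", {
    "condition_label": str, "conc_uM": float, "signal": float,
})
PHASE_COMPOSITION_SCHEMA = TableSchema("phase_composition", {
    "system_id": str, "c_tot_uM": float, "c_dil_uM": float,
    "phi": parse_fraction,
})
RATIO_SCHEMA = TableSchema("rate_ratios", {
    "S_uM": float, "ratio": float, "ratio_se": float, "n": int,
})
SNARF_CALIBRATION_SCHEMA = TableSchema("snarf_calibration", {
    "pH": float, "ratio": float,
})
SNARF_MEASUREMENT_SCHEMA = TableSchema("snarf_measurements", {
    "pH_nominal": float, "phase": str, "replicate_id": str, "ratio": float,
})


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a delimited-text table against a schema.

    Raises :class:`SchemaError` naming any missing required column, or
    the (1-based data) row and column of the first unparseable cell.
    Row order and extra columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, skipinitialspace=True)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing} for "
            f"schema {schema.name!r}"
        )
    out = df.copy()
    for col, parser in schema.columns.items():
        parsed = []
        for row_idx, raw in enumerate(df[col], start=1):
            try:
                parsed.append(parser(raw))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path.name}: cannot parse cell at row {row_idx}, "
                    f"column {col!r}: {raw!r}"
                ) from exc
        out[col] = parsed
    return out


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a table with a provenance comment header.

    The header records the package version plus any supplied metadata
    (seed, config hash, ...), one ``# key: value`` line each.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"phasekin_version": __version__}
    header.update(meta or {})
    buf = _io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
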