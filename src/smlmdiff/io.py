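"""Table and key-value file I/O.

All tables are comma-delimited text with a header row; distances are stored
in nm in files and converted to um at analysis boundaries. Numeric columns
round-trip at full double precision (values are written with ``repr``-exact
formatting). Model and fit results are serialized as flat ``key = value``
text files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "read_keyvalues", "write_keyvalues"]

#: required columns per table kind
SCHEMAS: dict[str, list[str]] = {
    "localizations": ["x_nm", "y_nm", "frame", "sigma_loc_nm", "spot_sd_nm", "intensity"],
    "trajectories": ["traj_id", "frame", "x_nm", "y_nm"],
    "estimates": ["traj_id", "D_um2_s", "D_log", "intercept_um2", "traj_len"],
    "profile": ["r_inner_um", "r_outer_um", "D_geo_um2_s", "n"],
    "trace": ["t_s", "I_raw"],
}


class SchemaError(ValueError):
    """A table does not carry the columns its schema requires."""


def _check_schema(columns, schema: str | None) -> None:
    if schema is None:
        return
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    missing = [c for c in SCHEMAS[schema] if c not in columns]
    if missing:
        raise SchemaError(f"table is missing required columns: {', '.join(missing)}")


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a delimited table, optionally validating against a named schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df.columns, schema)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a table as CSV with lossless float formatting."""
    _check_schema(df.columns, schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_keyvalues(mapping: dict, path: str | Path) -> None:
    """Write a flat ``key = value`` text file (one pair per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return repr(float(v))
        if isinstance(v, (bool, np.bool_)):
            return str(bool(v))
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        return str(v)

    lines = []
    for key, value in mapping.items():
        if isinstance(value, (list, tuple, np.ndarray)):
            value = ",".join(fmt(v) for v in value)
        else:
            value = fmt(value)
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")


def read_keyvalues(path: str | Path) -> dict[str, str]:
    """Read a flat key-value file; values are returned as strings."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
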