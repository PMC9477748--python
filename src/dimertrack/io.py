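"""Readers and writers for the package's artifact formats.

Localization tables are plain CSV with a fixed header and deterministic
formatting (coordinates at 0.01 nm resolution), movies are multi-page 16-bit
TIFF, configs YAML, results JSON.  Writers are byte-deterministic; readers
validate and reject malformed input rather than coercing it.

Frame indices are 0-based everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParseError, SchemaError

__all__ = [
    "LOC_COLUMNS",
    "read_localizations",
    "write_localizations",
    "read_stack",
    "write_stack",
    "write_json",
    "read_json",
]

#: canonical column order of a localization table
LOC_COLUMNS = ["cell_id", "channel", "frame", "x_nm", "y_nm", "intensity", "background"]

_NUMERIC = {"frame": int, "x_nm": float, "y_nm": float,
            "intensity": float, "background": float}


def validate_localizations(table: pd.DataFrame, n_frames: int | None = None) -> pd.DataFrame:
    """Validate schema and invariants of an in-memory localization table."""
    for col in LOC_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"localization table is missing column '{col}'")
    bad = set(table["channel"].unique()) - {"A", "B"}
    if bad:
        raise SchemaError(f"invalid channel values: {sorted(bad)} (expected A or B)")
    frames = table["frame"].to_numpy()
    if len(frames) and (np.any(frames < 0) or (n_frames is not None and np.any(frames >= n_frames))):
        raise SchemaError("frame indices out of range")
    for col in ("x_nm", "y_nm", "intensity", "background"):
        vals = table[col].to_numpy(dtype=float)
        if len(vals) and not np.all(np.isfinite(vals)):
            raise SchemaError(f"non-finite values in column '{col}'")
    return table[LOC_COLUMNS]


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read and validate a localization CSV.

    Raises
    ------
    SchemaError
        Missing required column or invalid channel/frame values.
    ParseError
        Non-numeric entry; the message names the first offending data row
        (1-based, excluding the header).
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in LOC_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing column '{col}'")
    out = table[LOC_COLUMNS].copy()
    for col, typ in _NUMERIC.items():
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & (out[col] != "")
        empty = out[col] == ""
        if bad.any() or empty.any():
            row = int(np.nonzero((bad | empty).to_numpy())[0][0]) + 1
            raise ParseError(
                f"{path}: non-numeric value {out[col].iloc[row - 1]!r} "
                f"in column '{col}' at data row {row}"
            )
        out[col] = converted.astype(typ)
    return validate_localizations(out)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as CSV (deterministic bytes).

    Column order is fixed; coordinates are formatted to 0.01 nm and
    intensities/backgrounds to 3 decimals.
    """
    out = validate_localizations(table).copy()
    for col in ("x_nm", "y_nm"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    for col in ("intensity", "background"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False, lineterminator="\n")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single-channel multi-page TIFF as an (n_frames, h, w) array.

    Raises :class:`FormatError` for truncated files or inconsistent frame
    shapes instead of returning a partial stack.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
            data = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises assorted exceptions on corruption
        raise FormatError(f"{path}: cannot read TIFF stack ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2D multi-page stack, got shape {data.shape}")
    return data


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write an (n_frames, h, w) uint16 stack as multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise FormatError(f"expected (n_frames, h, w) stack, got shape {stack.shape}")
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="minisblack")


def write_json(obj: dict, path: str | Path) -> None:
    """Write a results document deterministically (fixed key order, LF)."""
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
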