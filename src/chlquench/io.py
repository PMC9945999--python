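"""File formats: energy/coupling CSV tables and extended-XYZ charge files.

The CSV schemas match what an external MD + semiempirical engine would
dump: one row per trajectory frame.  Extended XYZ is the minimal dialect —
atom count, a comment line (``key=value`` pairs), then
``element x y z [charge]`` columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import COUPLING_COLUMNS, ENERGY_COLUMNS

__all__ = [
    "write_energy_table",
    "validate_energy_table",
    "write_coupling_table",
    "read_coupling_table",
    "write_xyz",
    "read_xyz",
]


def write_energy_table(table: pd.DataFrame, path: str | Path) -> None:
    table[ENERGY_COLUMNS].to_csv(path, index=False)


def validate_energy_table(path: str | Path) -> pd.DataFrame:
    """Load a per-frame state-energy CSV, enforcing the schema.

    Checks the header, finiteness of every energy, and strictly increasing,
    duplicate-free frame indices; raises ValueError naming the offending
    column or row.  Returns the validated DataFrame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no frames (empty file)") from exc
    for col in ENERGY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(table) == 0:
        raise ValueError(f"{path}: no frames")
    for col in ENERGY_COLUMNS[1:]:
        bad = ~np.isfinite(table[col].to_numpy(dtype=float))
        if bad.any():
            row = int(np.argmax(bad))
            raise ValueError(
                f"{path}: non-finite value in column {col!r} at row {row}"
            )
    frames = table["frame"].to_numpy()
    if len(np.unique(frames)) != len(frames):
        raise ValueError(f"{path}: duplicate frame indices")
    if not np.all(np.diff(frames) > 0):
        raise ValueError(f"{path}: frame indices must increase monotonically")
    return table


def write_coupling_table(table: pd.DataFrame, path: str | Path) -> None:
    table[COUPLING_COLUMNS].to_csv(path, index=False)


def read_coupling_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in COUPLING_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in COUPLING_COLUMNS[1:]:
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{path}: non-finite coupling in {col!r}")
        if np.any(vals < 0):
            raise ValueError(f"{path}: negative coupling magnitude in {col!r}")
    return table


def write_xyz(
    path: str | Path,
    elements: list[str],
    positions: np.ndarray,
    charges: np.ndarray | None = None,
    comment: dict | None = None,
) -> None:
    """Write an (extended) XYZ file; a charge column is appended when given."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(elements) != len(positions):
        raise ValueError("one element label per position required")
    parts = []
    if comment:
        parts = [f"{k}={v}" for k, v in comment.items()]
    lines = [str(len(elements)), " ".join(parts)]
    for i, (el, pos) in enumerate(zip(elements, positions)):
        row = f"{el} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f}"
        if charges is not None:
            row += f" {charges[i]:.8f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> dict:
    """Read an (extended) XYZ file.

    Returns a dict with ``elements``, ``positions`` (n, 3), ``charges``
    (n,) or None, and ``comment`` (key=value pairs parsed from line 2).
    """
    text = Path(path).read_text().strip().splitlines()
    if len(text) < 2:
        raise ValueError(f"{path}: not an XYZ file")
    n = int(text[0])
    comment = {}
    for token in text[1].split():
        if "=" in token:
            key, _, value = token.partition("=")
            comment[key] = value
    body = text[2 : 2 + n]
    if len(body) != n:
        raise ValueError(f"{path}: expected {n} atom lines, got {len(body)}")
    elements, positions, charges = [], [], []
    has_charge = None
    for line in body:
        fields = line.split()
        if len(fields) not in (4, 5):
            raise ValueError(f"{path}: malformed atom line {line!r}")
        if has_charge is None:
            has_charge = len(fields) == 5
        elif has_charge != (len(fields) == 5):
            raise ValueError(f"{path}: inconsistent column count")
        elements.append(fields[0])
        positions.append([float(v) for v in fields[1:4]])
        if has_charge:
            charges.append(float(fields[4]))
    return {
        "elements": elements,
        "positions": np.asarray(positions),
        "charges": np.asarray(charges) if has_charge else None,
        "comment": comment,
    }
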