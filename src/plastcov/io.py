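"""Shared table readers/writers and run manifests.

Everything on disk is plain text: CSV/TSV matrices with a header row of
labels, JSON manifests with seeds and per-file checksums — diff-able and
reproducible by construction.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .deconfound import ChangeMatrix


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(
    path: str | Path,
    index_col: str | int | None = 0,
    numeric: bool = True,
) -> pd.DataFrame:
    """Read a labeled CSV/TSV table; delimiter inferred from the extension.

    Duplicate column labels and non-numeric cells in numeric mode raise with
    coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    # pandas silently mangles duplicate headers, so check the raw header row
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_delimiter(path))
    seen: set[str] = set()
    dups = sorted({h for h in header if h in seen or seen.add(h)})
    if dups:
        raise ValueError(f"duplicated column labels in {path.name}: {dups}")
    df = pd.read_csv(path, sep=_delimiter(path), index_col=index_col)
    if numeric:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"non-numeric cell in {path.name} at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=index)
    return path


def write_change_matrix(m: ChangeMatrix, path: str | Path) -> Path:
    return write_table(m.values, path)


def read_change_matrix(path: str | Path, state: str) -> ChangeMatrix:
    return ChangeMatrix(read_table(path), state=state)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, payload: dict) -> Path:
    """Write a run manifest with sha256 checksums of every text output."""
    out_dir = Path(out_dir)
    checksums = {
        p.name: file_checksum(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.suffix in (".csv", ".tsv", ".json", ".yaml") and p.name != "manifest.json"
    }
    manifest = dict(payload, checksums=checksums)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
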