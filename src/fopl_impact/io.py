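"""CSV/YAML round-trip helpers for the pipeline tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["write_tables", "read_table", "bundle_hash", "write_manifest"]

#: boolean columns per table, restored on read
_BOOL_COLS = {"foods": ["exempt"], "branded": ["exempt"],
              "symbols": ["high_sodium", "high_sugars", "high_satfat", "exempt"]}


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write each table as ``<name>.csv`` under ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_table(path, name: str | None = None) -> pd.DataFrame:
    path = Path(path)
    name = name or path.stem
    df = pd.read_csv(path)
    for col in _BOOL_COLS.get(name, []):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def bundle_hash(paths) -> str:
    """SHA-256 over the byte content of the given files, in sorted order."""
    h = hashlib.sha256()
    for p in sorted(Path(p) for p in paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, out_dir) -> Path:
    p = Path(out_dir) / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return p
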