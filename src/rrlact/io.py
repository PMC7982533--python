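"""File formats, run configuration and manifests for the pipeline.

Everything is plain CSV/YAML/JSON: test-day records and pedigrees come in as
headered CSV (column schema below), solutions and genetic-parameter reports
go out as CSV with full numeric precision, and every run writes a manifest
(config, package version, seed) next to its outputs so a run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rrlact.pedigree import read_pedigree_csv, write_pedigree_csv

__all__ = [
    "RECORD_COLUMNS",
    "read_records",
    "write_records",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "write_manifest",
    "load_config",
]

#: Required record columns and their parsers.
RECORD_COLUMNS = {
    "animal": int,
    "parity": int,
    "dim": int,
    "yield_kg": float,
    "herd": int,
    "test_date": str,
    "calving_date": str,
    "age_months": float,
    "ecotype": int,
    "year": int,
    "season": int,
}


@dataclass
class RecordReadReport:
    """Rows rejected while reading, with 1-based line numbers and reasons."""

    n_read: int = 0
    rejected: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return not self.rejected


def read_records(path) -> tuple[pd.DataFrame, RecordReadReport]:
    """Read a test-day record CSV, collecting malformed rows into a report.

    Raises on missing columns (naming them); individual unparseable rows are
    dropped and listed with their line numbers instead of aborting the run.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"records file {path} missing column(s): {missing}")
    report = RecordReadReport(n_read=len(raw))
    parsed = {}
    bad = np.zeros(len(raw), dtype=bool)
    for col, typ in RECORD_COLUMNS.items():
        if typ is str:
            parsed[col] = raw[col]
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad |= vals.isna().to_numpy()
        parsed[col] = vals
    for i in np.flatnonzero(bad):
        report.rejected.append((int(i) + 2, "unparseable numeric field"))  # +2: header + 1-base
    df = pd.DataFrame(parsed)[~bad].reset_index(drop=True)
    for col, typ in RECORD_COLUMNS.items():
        if typ is int:
            df[col] = df[col].astype(int)
        elif typ is float:
            df[col] = df[col].astype(float)
    return df, report


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def write_manifest(out_dir, config: dict, seed: int | None = None) -> Path:
    """Write the reproducibility manifest (config + version + seed) as JSON."""
    from rrlact import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rrlact",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_matrix_csv(M: np.ndarray, path, name: str) -> None:
    """Write a small symmetric matrix with labelled coefficient indices."""
    M = np.asarray(M)
    idx = [f"{name}{i}" for i in range(M.shape[0])]
    pd.DataFrame(M, index=idx, columns=idx).to_csv(path, float_format="%.12g")
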