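"""Readers and writers for the package's plain-text formats.

Formats are deliberately simple: comma-separated, period decimal, UTF-8,
header required.  Fermentation records round-trip losslessly (17 significant
digits); SAXS curves use whitespace-separated ``q I sigma`` columns with
``#``-prefixed header lines carrying ``key: value`` metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bioreactor import RECORD_COLUMNS, FermentationRecord
from .particles import CELL_COLUMNS, PARTICLE_COLUMNS, ParticleDataset
from .saxs import SAXSCurve

__all__ = [
    "write_record",
    "read_record",
    "write_particles",
    "read_particles",
    "write_saxs",
    "read_saxs",
    "write_trace",
]

_FLOAT_FMT = "%.17g"


def write_record(record: FermentationRecord, path: str | Path) -> Path:
    """Write the canonical record CSV plus a sidecar metadata JSON."""
    path = Path(path)
    record.frame[RECORD_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(record.metadata, indent=1, default=str))
    return path


def read_record(path: str | Path) -> FermentationRecord:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    t = frame["time_h"].to_numpy()
    dup = np.nonzero(np.diff(t) == 0)[0]
    if len(dup):
        raise ValueError(f"{path.name}: duplicate timestamp at row {int(dup[0]) + 2}")
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path.name}: time column is not increasing")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FermentationRecord(frame, metadata)


def write_particles(dataset: ParticleDataset, particles_path: str | Path,
                    cells_path: str | Path | None = None) -> None:
    Path(particles_path).parent.mkdir(parents=True, exist_ok=True)
    dataset.particles[PARTICLE_COLUMNS].to_csv(
        particles_path, index=False, float_format=_FLOAT_FMT
    )
    if cells_path is not None and len(dataset.cells):
        dataset.cells[CELL_COLUMNS].to_csv(cells_path, index=False, float_format=_FLOAT_FMT)


def read_particles(particles_path: str | Path,
                   cells_path: str | Path | None = None) -> ParticleDataset:
    p = pd.read_csv(particles_path, float_precision="round_trip")
    missing = [c for c in PARTICLE_COLUMNS if c not in p.columns]
    if missing:
        raise ValueError(f"{Path(particles_path).name}: missing column(s) {missing}")
    if cells_path is not None:
        c = pd.read_csv(cells_path, float_precision="round_trip")
        missing = [col for col in CELL_COLUMNS if col not in c.columns]
        if missing:
            raise ValueError(f"{Path(cells_path).name}: missing column(s) {missing}")
    else:
        c = pd.DataFrame(columns=CELL_COLUMNS)
    return ParticleDataset(p, c)


def write_saxs(curve: SAXSCurve, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# magnetoferm SAXS curve: q [1/A], I, sigma"]
    for key, val in curve.metadata.items():
        if isinstance(val, (int, float, str)):
            lines.append(f"# {key}: {val}")
    for qq, ii, ss in zip(curve.q, curve.intensity, curve.sigma):
        lines.append(f"{qq:.17g} {ii:.17g} {ss:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_saxs(path: str | Path) -> SAXSCurve:
    """Parse a 3-column ASCII .dat curve; ``# key: value`` headers kept."""
    path = Path(path)
    meta: dict = {}
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                val = val.strip()
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path.name}:{lineno}: expected 'q I [sigma]' columns")
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-numeric value") from exc
        rows.append(vals + [0.0] * (3 - len(vals)))
    if not rows:
        raise ValueError(f"{path.name}: no data rows (headers only?)")
    arr = np.array(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError(f"{path.name}: q column must be strictly increasing")
    return SAXSCurve(arr[:, 0], arr[:, 1], arr[:, 2], meta)


def write_trace(frame: pd.DataFrame, path: str | Path) -> Path:
    """Controller trace CSV: time_h,dO2_pct,output_pct,rpm,airflow_slpm."""
    cols = ["time_h", "dO2_pct", "output_pct", "rpm", "airflow_slpm"]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"trace is missing column(s) {missing}")
    path = Path(path)
    frame[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
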