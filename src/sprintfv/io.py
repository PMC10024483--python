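"""CSV interchange for radar traces and study manifests.

Trace files are two-column CSVs with header ``time_s,velocity_ms``, one file
per trial, named ``{athlete}_{session}_{trial}.csv``.  A manifest CSV with
columns ``athlete,group,session,trial,file,mass_kg,stature_m`` maps files to
athletes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SyntheticAthlete
from .errors import ValidationError
from .fitting import RadarTrace

__all__ = [
    "TRACE_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "export_study",
]

TRACE_COLUMNS = ["time_s", "velocity_ms"]
MANIFEST_COLUMNS = ["athlete", "group", "session", "trial", "file", "mass_kg", "stature_m"]


def write_trace(trace: RadarTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


def read_trace(path: str | Path, **meta) -> RadarTrace:
    """Read a trace CSV; extra keyword metadata is attached to the trace."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return RadarTrace(
        time=df["time_s"].to_numpy(float), velocity=df["velocity_ms"].to_numpy(float), **meta
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a study manifest.

    Raises :class:`ValidationError` naming offending rows for missing
    columns, empty manifests and duplicate athlete-session-trial keys.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: manifest is empty")
    dup = df.duplicated(subset=["athlete", "session", "trial"], keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate athlete-session-trial keys in rows {df.index[dup].tolist()}"
        )
    return df


def export_study(
    traces: list[RadarTrace],
    cohort: list[SyntheticAthlete],
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write a synthetic study as trace CSVs + manifest + ground-truth JSON.

    Emits exactly the interchange format :func:`read_manifest` /
    :func:`read_trace` consume, plus ``ground_truth.json`` for recovery
    tests.  Returns (manifest path, ground-truth path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {sa.athlete.athlete_id: sa for sa in cohort}
    rows = []
    for tr in traces:
        fname = f"{tr.athlete_id}_{tr.session}_{tr.trial_index}.csv"
        write_trace(tr, outdir / fname)
        sa = by_id[tr.athlete_id]
        rows.append(
            {
                "athlete": tr.athlete_id,
                "group": sa.group,
                "session": tr.session,
                "trial": tr.trial_index,
                "file": fname,
                "mass_kg": sa.athlete.body_mass,
                "stature_m": sa.athlete.stature,
            }
        )
    manifest_path = write_manifest(pd.DataFrame(rows), outdir / "manifest.csv")
    truth = {
        sa.athlete.athlete_id: {
            "group": sa.group,
            "pre": {"F0_rel": sa.pre.f0_rel, "v0": sa.pre.v0},
            "post": None
            if sa.post is None
            else {"F0_rel": sa.post.f0_rel, "v0": sa.post.v0},
        }
        for sa in cohort
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return manifest_path, truth_path
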