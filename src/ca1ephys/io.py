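"""Plain-text file formats: trace CSV + JSON sidecar, cohort bundles,
feature tables and fit results.

A trace is stored as ``<stem>.csv`` with columns ``time_ms,voltage_mV`` and a
``<stem>.json`` sidecar holding the stimulus, identifiers, dt and bias
current.  The pair round-trips exactly at the printed precision.  A cohort
bundle is a directory of per-cell trace files plus ``manifest.json`` (ground
truth) and ``cohort_spec.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biophys import StimulusStep, Trace
from .features import CellSweeps

__all__ = ["write_trace", "read_trace", "write_cohort", "read_cohort",
           "write_feature_table", "read_feature_table", "TraceFormatError"]

VOLTAGE_DECIMALS = 6


class TraceFormatError(ValueError):
    """Malformed trace file (reported with the offending path/line)."""


def write_trace(trace: Trace, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    t = trace.time
    with open(csv_path, "w") as fh:
        fh.write("time_ms,voltage_mV\n")
        for ti, vi in zip(t, trace.voltage):
            fh.write(f"{ti:.6g},{vi:.{VOLTAGE_DECIMALS}f}\n")
    sidecar = {
        "dt": trace.dt,
        "cell_id": trace.cell_id,
        "group_label": trace.group_label,
        "sweep_id": trace.sweep_id,
        "hold_current_pA": trace.hold_current_pA,
        "stimulus": dataclasses.asdict(trace.stimulus),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_trace(stem: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises TraceFormatError naming the file (and line, where known) for a
    missing sidecar, malformed rows or a non-uniform time grid.
    """
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    if not json_path.exists():
        raise TraceFormatError(f"missing sidecar: expected {json_path}")
    if not csv_path.exists():
        raise TraceFormatError(f"missing trace data: expected {csv_path}")
    sidecar = json.loads(json_path.read_text())

    times, volts = [], []
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != "time_ms,voltage_mV":
            raise TraceFormatError(f"{csv_path}:1: bad header {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                a, b = line.split(",")
                times.append(float(a))
                volts.append(float(b))
            except ValueError as err:
                raise TraceFormatError(f"{csv_path}:{ln}: {err}") from None
    t = np.asarray(times)
    dt = float(sidecar["dt"])
    if t.size >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TraceFormatError(f"{csv_path}: non-uniform time grid")
        if not np.isclose(steps[0], dt, rtol=1e-6):
            raise TraceFormatError(
                f"{csv_path}: grid step {steps[0]} != sidecar dt {dt}")
    stim = StimulusStep(**sidecar["stimulus"])
    return Trace(dt=dt, voltage=np.asarray(volts), stimulus=stim,
                 cell_id=sidecar.get("cell_id", ""),
                 group_label=sidecar.get("group_label", ""),
                 sweep_id=sidecar.get("sweep_id", ""),
                 hold_current_pA=sidecar.get("hold_current_pA"))


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------

def write_cohort(cohort, outdir: str | Path) -> Path:
    """Write a cohort bundle (trace files per cell + manifest + spec echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cell in cohort.cells:
        cdir = outdir / cell.cell_id
        cdir.mkdir(exist_ok=True)
        for tr in cell.traces:
            write_trace(tr, cdir / tr.sweep_id)
        if cell.rmp_trace is not None:
            write_trace(cell.rmp_trace, cdir / "rmp")
    (outdir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1,
                                                     sort_keys=True))
    spec = cohort.spec
    spec_doc = {
        "master_seed": spec.master_seed, "dt": spec.dt,
        "amplitudes": list(spec.amplitudes) if spec.amplitudes else None,
        "groups": [{
            "label": g.label, "n_cells": g.n_cells, "cv": g.cv,
            "noise_sd": g.noise_sd, "params": g.params,
            "sag_targets": g.sag_targets,
            "spiking": {
                "rheobase_pA": g.spiking.rheobase_pA,
                "fi_slope": g.spiking.fi_slope,
                "adaptation_ratio": g.spiking.adaptation_ratio,
                "template": dataclasses.asdict(g.spiking.template),
            },
        } for g in spec.groups],
    }
    (outdir / "cohort_spec.json").write_text(json.dumps(spec_doc, indent=1,
                                                        sort_keys=True))
    return outdir


def read_cohort(indir: str | Path) -> tuple[list[CellSweeps], dict]:
    """Read back a cohort bundle; returns (cells, manifest)."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    cells = []
    for cdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        traces, rmp = [], None
        for csv_path in sorted(cdir.glob("*.csv")):
            tr = read_trace(csv_path.with_suffix(""))
            if csv_path.stem == "rmp":
                rmp = tr
            else:
                traces.append(tr)
        if traces:
            cells.append(CellSweeps(cell_id=cdir.name,
                                    group_label=traces[0].group_label,
                                    traces=traces, rmp_trace=rmp))
    return cells, manifest


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=[0, 1])
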