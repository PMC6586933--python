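"""Readers and writers for every on-disk artifact of the pipeline.

Traces, stimulus schedules and response-call tables travel as plain UTF-8
CSV (time in seconds, '.' decimal separator); image stacks as multi-page
TIFF with a single-page 16-bit label mask (0 = background).  All readers
validate their inputs and fail with errors naming the offending field —
no silent coercion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "StimulusEpoch",
    "Recording",
    "read_traces",
    "write_traces",
    "read_schedule",
    "write_schedule",
    "extract_rois",
    "read_stack",
    "write_stack",
    "write_calls",
    "read_calls",
    "load_config",
]

EPOCH_ROLES = ("viability_control", "test", "vehicle_control", "calibration")

#: maximum tolerated NaN fraction per trace
MAX_NAN_FRACTION = 0.05


@dataclass(frozen=True)
class StimulusEpoch:
    """One bath application: compound, concentration and valve timing."""

    epoch_id: int
    compound: str
    concentration: float  # mM (uM expressed as mM)
    valve_open: float  # s, time the perfusion valve opens
    duration: float  # s, application duration
    role: str = "test"

    def __post_init__(self) -> None:
        if self.role not in EPOCH_ROLES:
            raise ValueError(
                f"epoch {self.epoch_id}: role {self.role!r} not in {EPOCH_ROLES}"
            )
        if self.concentration < 0:
            raise ValueError(f"epoch {self.epoch_id}: concentration must be >= 0")
        if self.compound.lower() == "ringer" and self.concentration != 0:
            raise ValueError(f"epoch {self.epoch_id}: Ringer epochs have concentration 0")
        if self.duration <= 0:
            raise ValueError(f"epoch {self.epoch_id}: duration must be > 0")


@dataclass
class Recording:
    """Raw fluorescence traces of one slice experiment.

    ``traces`` is (n_cells, n_time) arbitrary-unit fluorescence; ``time`` is
    seconds, strictly increasing and uniform to within ~1% jitter.
    """

    time: np.ndarray
    traces: np.ndarray
    cell_ids: list
    schedule: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.cell_ids = [str(c) for c in self.cell_ids]
        validate_recording(self)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_time(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def sorted_schedule(self) -> list:
        return sorted(self.schedule, key=lambda e: e.valve_open)


def validate_recording(rec: Recording) -> None:
    if np.isnan(rec.time).any():
        raise ValueError("time: contains NaN")
    d = np.diff(rec.time)
    if rec.time.size >= 2 and not (d > 0).all():
        raise ValueError("time: must be strictly increasing")
    if rec.time.size >= 3:
        med = np.median(d)
        if np.abs(d - med).max() > 0.01 * med + 1e-12:
            raise ValueError("time: sampling not uniform within 1% jitter tolerance")
    if rec.traces.shape[1] != rec.time.size:
        raise ValueError(
            f"traces: {rec.traces.shape[1]} columns but {rec.time.size} time points"
        )
    if len(rec.cell_ids) != rec.traces.shape[0]:
        raise ValueError("cell_ids: length does not match number of trace rows")
    if len(set(rec.cell_ids)) != len(rec.cell_ids):
        raise ValueError("cell_ids: not unique")
    nan_frac = np.isnan(rec.traces).mean(axis=1)
    if (nan_frac > MAX_NAN_FRACTION).any():
        bad = [c for c, f in zip(rec.cell_ids, nan_frac) if f > MAX_NAN_FRACTION]
        raise ValueError(f"traces: >{MAX_NAN_FRACTION:.0%} NaN in cells {bad}")
    if rec.schedule:
        epochs = sorted(rec.schedule, key=lambda e: e.valve_open)
        ids = [e.epoch_id for e in epochs]
        if len(set(ids)) != len(ids):
            raise ValueError("schedule: epoch_id not unique")
        for a, b in zip(epochs, epochs[1:]):
            if a.valve_open + a.duration > b.valve_open:
                raise ValueError(
                    f"schedule: epochs {a.epoch_id} and {b.epoch_id} overlap"
                )
        t0, t1 = rec.time[0], rec.time[-1]
        for e in epochs:
            if e.valve_open < t0 or e.valve_open + e.duration > t1:
                raise ValueError(
                    f"schedule: epoch {e.epoch_id} lies outside the recorded time range"
                )


# ---------------------------------------------------------------------------
# schedules


def write_schedule(schedule: Sequence[StimulusEpoch], path) -> None:
    df = pd.DataFrame(
        [
            {
                "epoch_id": e.epoch_id,
                "compound": e.compound,
                "concentration_mM": e.concentration,
                "valve_open_s": e.valve_open,
                "duration_s": e.duration,
                "role": e.role,
            }
            for e in schedule
        ],
        columns=["epoch_id", "compound", "concentration_mM", "valve_open_s", "duration_s", "role"],
    )
    df.to_csv(path, index=False)


def read_schedule(path) -> list:
    df = pd.read_csv(path)
    required = {"epoch_id", "compound", "concentration_mM", "valve_open_s", "duration_s", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule file {path}: missing columns {sorted(missing)}")
    return [
        StimulusEpoch(
            epoch_id=int(r.epoch_id),
            compound=str(r.compound),
            concentration=float(r.concentration_mM),
            valve_open=float(r.valve_open_s),
            duration=float(r.duration_s),
            role=str(r.role),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# trace tables


def write_traces(rec: Recording, path) -> None:
    """Wide CSV: a ``time_s`` column followed by one column per cell."""
    df = pd.DataFrame({"time_s": rec.time})
    for cid, row in zip(rec.cell_ids, rec.traces):
        df[cid] = row
    df.to_csv(path, index=False)


def read_traces(path, schedule_path=None, dialect: str = "wide") -> Recording:
    """Read a trace table (wide: time_s + one column per cell; long:
    time_s, cell_id, F).  A schedule sidecar ``<stem>.schedule.csv`` is
    attached automatically when present and no explicit path is given."""
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "long":
        for col in ("time_s", "cell_id", "F"):
            if col not in df.columns:
                raise ValueError(f"{path}: long dialect requires column {col!r}")
        wide = df.pivot(index="time_s", columns="cell_id", values="F")
        time = wide.index.to_numpy(dtype=float)
        traces = wide.to_numpy(dtype=float).T
        cell_ids = [str(c) for c in wide.columns]
    elif dialect == "wide":
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: missing time column 'time_s'")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: no trace columns besides time_s")
        time = df["time_s"].to_numpy(dtype=float)
        cell_ids = [c for c in df.columns if c != "time_s"]
        traces = df[cell_ids].to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if pd.Series(time).duplicated().any():
        raise ValueError(f"{path}: duplicate time stamps")

    schedule = []
    if schedule_path is None:
        cand = path.with_name(path.stem + ".schedule.csv")
        if cand.exists():
            schedule = read_schedule(cand)
    else:
        schedule = read_schedule(schedule_path)
    return Recording(time=time, traces=traces, cell_ids=cell_ids, schedule=schedule)


# ---------------------------------------------------------------------------
# stacks and ROI masks


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    m = np.asarray(mask)
    if m.min() < 0:
        raise ValueError("mask: labels must be non-negative")
    tifffile.imwrite(path, m.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path)


def extract_rois(stack: np.ndarray, mask: np.ndarray, schedule=(), time=None,
                 sampling_rate: float = 1.0) -> Recording:
    """Mean pixel value per positive mask label, per frame.

    Label order is preserved as cell order (permutation-equivariant: a
    relabelling of the mask permutes the output rows correspondingly).
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.ndim != 3:
        raise ValueError("stack: expected (frames, y, x)")
    if stack.shape[1:] != mask.shape:
        raise ValueError(
            f"stack frame shape {stack.shape[1:]} != mask shape {mask.shape}"
        )
    if mask.min() < 0:
        raise ValueError("mask: labels must be non-negative integers")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    n_frames = stack.shape[0]
    if time is None:
        time = np.arange(n_frames) / float(sampling_rate)
    traces = np.empty((labels.size, n_frames))
    flat_mask = mask.ravel()
    flat = stack.reshape(n_frames, -1)
    for j, lab in enumerate(labels):
        sel = flat_mask == lab
        traces[j] = flat[:, sel].mean(axis=1)
    return Recording(
        time=np.asarray(time, float),
        traces=traces,
        cell_ids=[str(int(l)) for l in labels],
        schedule=list(schedule),
    )


# ---------------------------------------------------------------------------
# response-call tables

CALL_COLUMNS = [
    "cell_id",
    "epoch_id",
    "compound",
    "responsive",
    "peak_dff",
    "peak_time_s",
    "onset_time_s",
    "onset_delay_s",
    "suprathreshold_duration_s",
    "threshold_dff",
    "exclusion_reason",
]


def write_calls(calls, path) -> None:
    """Long-format CSV, one row per (cell, epoch).  ``calls`` is a sequence
    of ResponseCall; an empty sequence yields a header-only file."""
    rows = []
    for c in calls:
        rows.append(
            {
                "cell_id": c.cell_id,
                "epoch_id": c.epoch_id,
                "compound": c.compound,
                "responsive": bool(c.responsive),
                "peak_dff": c.peak_dff,
                "peak_time_s": c.peak_time,
                "onset_time_s": c.onset_time,
                "onset_delay_s": c.onset_delay,
                "suprathreshold_duration_s": c.suprathreshold_duration,
                "threshold_dff": c.threshold,
                "exclusion_reason": c.exclusion_reason,
            }
        )
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, index=False)


def read_calls(path):
    from .calling import ResponseCall  # local import avoids a cycle

    df = pd.read_csv(path)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls file {path}: missing columns {sorted(missing)}")

    def _f(v):
        return None if pd.isna(v) else float(v)

    return [
        ResponseCall(
            cell_id=str(r.cell_id),
            epoch_id=int(r.epoch_id),
            compound=str(r.compound),
            responsive=bool(r.responsive),
            peak_dff=_f(r.peak_dff),
            peak_time=_f(r.peak_time_s),
            onset_time=_f(r.onset_time_s),
            onset_delay=_f(r.onset_delay_s),
            suprathreshold_duration=_f(r.suprathreshold_duration_s),
            threshold=_f(r.threshold_dff),
            exclusion_reason=str(r.exclusion_reason),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# configuration files


def load_config(path) -> dict:
    """YAML or JSON config file -> dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
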