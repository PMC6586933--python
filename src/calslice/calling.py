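"""Three-criterion responsiveness classification.

A (cell, epoch) pair is responsive iff a run of consecutive samples, all
strictly above the prestimulus mean + k*SD threshold, begins within the
post-valve search window and spans at least ``min_duration`` seconds; the
cell additionally must show no Ringer response and no spontaneous
activity (those cells are excluded from tastant analysis entirely).

The prestimulus window is the 15 s immediately before valve opening,
re-anchored per stimulus; the SD is the n-1 sample estimator; samples
exactly at the threshold do not count.  Run span is counted inclusively,
(last - first sample time) + one sample period, so a 5 s square pulse at
2 Hz satisfies a 5 s minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Recording, StimulusEpoch
from .preprocessing import NormalizedRecording

__all__ = [
    "CallParams",
    "ResponseCall",
    "epoch_threshold",
    "call_epoch",
    "detect_spontaneous",
    "apply_exclusions",
    "call_recording",
    "onset_delay_summary",
]

EXCLUSION_REASONS = (
    "none",
    "ringer_responsive",
    "spontaneous_activity",
    "insufficient_baseline",
)


@dataclass(frozen=True)
class CallParams:
    prestim_window: float = 15.0  # s
    k_sd: float = 3.0
    min_duration: float = 5.0  # s
    search_window: float = 60.0  # s after valve opening a response may begin
    ringer_policy: bool = True
    spontaneous_policy: bool = True
    min_spont_samples: int = 3
    min_baseline_samples: int = 5
    interpolate_onset: bool = True

    def __post_init__(self) -> None:
        if self.prestim_window <= 0 or self.k_sd <= 0 or self.min_duration <= 0:
            raise ValueError("prestim_window, k_sd and min_duration must be > 0")
        if self.search_window < self.min_duration:
            raise ValueError("search_window must be >= min_duration")


@dataclass
class ResponseCall:
    cell_id: str
    epoch_id: int
    compound: str
    responsive: bool
    peak_dff: float | None = None
    peak_time: float | None = None
    onset_time: float | None = None
    onset_delay: float | None = None
    suprathreshold_duration: float | None = None
    threshold: float | None = None
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.responsive and self.exclusion_reason != "none":
            raise ValueError("responsive calls cannot carry an exclusion reason")


def _prestim_selection(time, epoch, all_epochs, params):
    """Index selection for the prestimulus window, shifted earlier past any
    previous epoch's search window it would otherwise overlap."""
    end = epoch.valve_open
    prev_windows = sorted(
        (e.valve_open, e.valve_open + params.search_window)
        for e in all_epochs
        if e.valve_open < epoch.valve_open
    )
    for _ in range(len(prev_windows) + 1):
        start = end - params.prestim_window
        hit = [w for w in prev_windows if w[0] < end and w[1] > start]
        if not hit:
            break
        end = min(w[0] for w in hit)
    start = end - params.prestim_window
    return (time >= start) & (time < end)


def epoch_threshold(dff, time, epoch: StimulusEpoch, params: CallParams,
                    all_epochs=()):
    """(mean, sd, threshold) over the prestimulus window; n-1 SD.

    Returns None if fewer than ``min_baseline_samples`` clean samples exist
    (insufficient-baseline exclusion).
    """
    dff = np.asarray(dff, float)
    time = np.asarray(time, float)
    sel = _prestim_selection(time, epoch, all_epochs or [epoch], params)
    vals = dff[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size < params.min_baseline_samples:
        return None
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return mean, sd, mean + params.k_sd * sd


def _runs_above(above: np.ndarray):
    """(start, stop) index pairs of maximal consecutive True runs;
    stop is inclusive."""
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def call_epoch(dff, time, epoch: StimulusEpoch, params: CallParams,
               all_epochs=(), cell_id: str = "?") -> ResponseCall:
    """Classify one (cell, epoch) pair.

    ``responsive`` iff some strictly-supra-threshold consecutive run starts
    within [valve_open, valve_open + search_window] and spans at least
    ``min_duration``.  Onset is the threshold crossing of the earliest
    qualifying run; peak is the max dF/F0 over the search window.
    """
    dff = np.asarray(dff, float)
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    base = ResponseCall(cell_id=cell_id, epoch_id=epoch.epoch_id,
                        compound=epoch.compound, responsive=False)

    thr = epoch_threshold(dff, time, epoch, params, all_epochs)
    if thr is None:
        base.exclusion_reason = "insufficient_baseline"
        return base
    mean, sd, threshold = thr
    base.threshold = threshold

    win_start = epoch.valve_open
    win_end = epoch.valve_open + params.search_window
    if win_end > time[-1] + dt / 2:
        # truncated search window at the end of the recording
        win_end = time[-1]
        if win_end - win_start < params.min_duration:
            base.exclusion_reason = "insufficient_baseline"
            return base

    in_win = (time >= win_start) & (time <= win_end)
    if in_win.any():
        seg = dff[in_win]
        base.peak_dff = float(np.nanmax(seg))
        base.peak_time = float(time[in_win][int(np.nanargmax(seg))])

    above = np.zeros_like(dff, dtype=bool)
    valid = ~np.isnan(dff)
    above[valid] = dff[valid] > threshold
    qualifying = []
    for i, j in _runs_above(above):
        if not (win_start <= time[i] <= win_end):
            continue
        span = time[j] - time[i] + dt
        if span >= params.min_duration:
            qualifying.append((i, j, span))
    if not qualifying:
        return base

    i0, j0, _ = qualifying[0]
    onset_time = float(time[i0])
    if params.interpolate_onset and i0 > 0 and not np.isnan(dff[i0 - 1]) \
            and dff[i0 - 1] <= threshold and dff[i0] > dff[i0 - 1]:
        frac = (threshold - dff[i0 - 1]) / (dff[i0] - dff[i0 - 1])
        onset_time = float(time[i0 - 1] + frac * (time[i0] - time[i0 - 1]))
    base.responsive = True
    base.onset_time = onset_time
    base.onset_delay = max(onset_time - epoch.valve_open, 0.0)
    base.suprathreshold_duration = float(max(s for *_, s in qualifying))
    return base


def detect_spontaneous(dff, time, schedule, params: CallParams) -> bool:
    """Supra-threshold activity entirely outside all stimulus search windows.

    The threshold is rolling: mean + k*SD over the preceding
    ``prestim_window`` seconds, sample-count based.  A run of at least
    ``min_spont_samples`` consecutive supra-threshold samples lying wholly
    outside every [valve_open, valve_open + search_window] flags the cell.
    """
    dff = np.asarray(dff, float)
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    w = max(int(round(params.prestim_window / dt)), params.min_baseline_samples)

    n = dff.size
    above = np.zeros(n, dtype=bool)
    if n > w:
        # trailing window [i-w, i) for each sample i >= w
        wins = np.lib.stride_tricks.sliding_window_view(dff, w)[: n - w]
        counts = (~np.isnan(wins)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(wins, axis=1)
            sd = np.nanstd(wins, axis=1, ddof=1)
        thr = mean + params.k_sd * sd
        ok = counts >= params.min_baseline_samples
        v = dff[w:]
        above[w:] = ok & ~np.isnan(v) & (v > thr)

    outside = np.ones(n, dtype=bool)
    for e in schedule:
        outside &= ~((time >= e.valve_open) & (time <= e.valve_open + params.search_window))

    for i, j in _runs_above(above & outside):
        if j - i + 1 >= params.min_spont_samples:
            return True
    return False


def apply_exclusions(calls, normalized: NormalizedRecording,
                     params: CallParams):
    """Set exclusion flags per the vehicle-control and spontaneous-activity
    rules.  Cells responsive to Ringer, or with activity outside stimulus
    windows, have *all* their calls flagged (and forced non-responsive);
    exclusions never turn a non-responsive call responsive.
    """
    schedule = normalized.schedule
    ringer_epochs = [e for e in schedule if e.compound.lower() == "ringer"]
    if params.ringer_policy and not ringer_epochs:
        raise ValueError("ringer_policy is on but the schedule has no Ringer epoch")

    ringer_ids = {e.epoch_id for e in ringer_epochs}
    excluded: dict[str, str] = {}
    if params.ringer_policy:
        for c in calls:
            if c.epoch_id in ringer_ids and c.responsive:
                excluded[c.cell_id] = "ringer_responsive"
    if params.spontaneous_policy:
        for cid in normalized.cell_ids:
            if cid in excluded:
                continue
            if detect_spontaneous(normalized.trace(cid), normalized.time,
                                  schedule, params):
                excluded[cid] = "spontaneous_activity"

    out = []
    for c in calls:
        if c.cell_id in excluded:
            out.append(replace(c, responsive=False,
                               exclusion_reason=excluded[c.cell_id]))
        else:
            out.append(c)
    return out


def call_recording(normalized: NormalizedRecording, params: CallParams = CallParams(),
                   exclusions: bool = True):
    """All (cell, epoch) calls for a normalized recording, exclusion rules
    applied (unless disabled, e.g. for the bleach-fit first pass)."""
    epochs = sorted(normalized.schedule, key=lambda e: e.valve_open)
    calls = []
    for cid, trace in zip(normalized.cell_ids, normalized.dff):
        for e in epochs:
            calls.append(
                call_epoch(trace, normalized.time, e, params,
                           all_epochs=epochs, cell_id=cid)
            )
    if exclusions and (params.ringer_policy or params.spontaneous_policy):
        calls = apply_exclusions(calls, normalized, params)
    return calls


def onset_delay_summary(calls, compound: str):
    """(mean, sem, n) of onset delays over responsive calls for a compound.

    Returns (nan, nan, 0) when no responsive call exists, and sem = nan at
    n = 1 (a single delay has no dispersion estimate).
    """
    delays = np.array([
        c.onset_delay for c in calls
        if c.responsive and c.compound == compound and c.onset_delay is not None
    ])
    n = delays.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(delays.mean())
    sem = float(delays.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n
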