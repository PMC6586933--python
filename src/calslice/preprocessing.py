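"""Raw fluorescence -> bleach-corrected dF/F0.

F0 is the mean fluorescence before the first stimulus application;
dF/F0 = (F(t) - F0) / F0.  Photobleaching is corrected by dividing each
raw trace by a single-exponential decay fitted to the pooled mean of
per-F0-normalized non-responding traces (the decay observed in cells
that never respond), normalized to 1 at the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import Recording

__all__ = [
    "NormalizedRecording",
    "BleachFit",
    "compute_f0",
    "compute_dff",
    "fit_bleach",
    "correct_bleach",
    "normalize_recording",
]

MIN_BASELINE_SAMPLES = 5
TAU_PLAUSIBLE = (1.0, 1e5)  # s


class InsufficientBaselineError(ValueError):
    pass


class BleachFitError(RuntimeError):
    pass


@dataclass
class BleachFit:
    """Fitted decay F(t) = C + B*exp(-t/tau_b) on the mean normalized
    non-responder trace.  ``amplitude`` is the bleached fraction
    A = B0/(B0+C) with B0 the exponential term at the first sample."""

    amplitude: float
    tau_b: float
    C: float
    B: float
    t0: float
    rms_residual: float
    cell_ids: list = field(default_factory=list)
    plausible: bool = True

    def decay(self, time: np.ndarray) -> np.ndarray:
        """Decay curve normalized to 1 at t0."""
        d = self.C + self.B * np.exp(-np.asarray(time, float) / self.tau_b)
        return d / (self.C + self.B * np.exp(-self.t0 / self.tau_b))


@dataclass
class NormalizedRecording:
    """dF/F0 traces plus the raw recording they came from."""

    raw: Recording
    time: np.ndarray
    dff: np.ndarray
    f0: np.ndarray  # per retained cell
    cell_ids: list
    rejected: dict = field(default_factory=dict)  # cell_id -> reason
    bleach_fit: BleachFit | None = None
    corrected: bool = False

    @property
    def schedule(self):
        return self.raw.schedule

    def trace(self, cell_id: str) -> np.ndarray:
        return self.dff[self.cell_ids.index(cell_id)]


def _f0_window(recording: Recording) -> np.ndarray:
    sched = recording.sorted_schedule()
    if not sched:
        raise ValueError("recording has no stimulus schedule; F0 window undefined")
    first_valve = sched[0].valve_open
    sel = recording.time < first_valve
    if sel.sum() < MIN_BASELINE_SAMPLES:
        raise InsufficientBaselineError(
            f"only {int(sel.sum())} samples before the first stimulus "
            f"(need >= {MIN_BASELINE_SAMPLES})"
        )
    return sel


def compute_f0(recording: Recording):
    """Per-cell baseline: mean raw fluorescence before the first stimulus.

    Returns (f0 array, rejected dict) where cells with F0 <= 0 are
    rejected with a reason rather than propagated.
    """
    sel = _f0_window(recording)
    f0 = np.nanmean(recording.traces[:, sel], axis=1)
    rejected = {
        cid: "non_positive_f0"
        for cid, v in zip(recording.cell_ids, f0)
        if not (v > 0)
    }
    return f0, rejected


def compute_dff(recording: Recording, f0=None) -> NormalizedRecording:
    """Elementwise (F(t) - F0) / F0; cells with non-positive F0 dropped."""
    if f0 is None:
        f0, rejected = compute_f0(recording)
    else:
        f0 = np.asarray(f0, dtype=float)
        if f0.shape[0] != recording.n_cells:
            raise ValueError(
                f"f0 has {f0.shape[0]} entries for {recording.n_cells} cells"
            )
        rejected = {
            cid: "non_positive_f0"
            for cid, v in zip(recording.cell_ids, f0)
            if not (v > 0)
        }
    keep = np.array([cid not in rejected for cid in recording.cell_ids])
    f0k = f0[keep]
    dff = recording.traces[keep] / f0k[:, None] - 1.0
    return NormalizedRecording(
        raw=recording,
        time=recording.time,
        dff=dff,
        f0=f0k,
        cell_ids=[c for c in recording.cell_ids if c not in rejected],
        rejected=rejected,
    )


def fit_bleach(recording: Recording, non_responder_ids, search_window: float = 60.0,
               exclude_epoch_windows: bool = True) -> BleachFit:
    """Least-squares single-exponential fit to the pooled mean of
    per-F0-normalized non-responder traces.

    Samples inside any epoch's [valve_open, valve_open + search_window]
    are excluded from the fit (guards against sub-threshold stimulus
    contamination even in nominal non-responders).
    """
    ids = [c for c in recording.cell_ids if c in set(non_responder_ids)]
    if len(ids) < 3:
        raise BleachFitError(
            f"need >= 3 non-responding cells for the bleach fit, got {len(ids)}"
        )
    f0, rejected = compute_f0(recording)
    idx = [recording.cell_ids.index(c) for c in ids if c not in rejected]
    if len(idx) < 3:
        raise BleachFitError("fewer than 3 non-responders with positive F0")
    norm = recording.traces[idx] / f0[idx, None]
    mean_trace = np.nanmean(norm, axis=0)
    time = recording.time

    mask = np.ones_like(time, dtype=bool)
    if exclude_epoch_windows:
        for e in recording.schedule:
            mask &= ~((time >= e.valve_open) & (time <= e.valve_open + search_window))
    t, y = time[mask], mean_trace[mask]
    if t.size < 20:
        raise BleachFitError(f"only {t.size} samples available for the bleach fit")

    # initial guesses: offset from the last decile, amplitude from the first
    k = max(t.size // 10, 1)
    c0 = float(np.mean(y[-k:]))
    b0 = float(np.mean(y[:k]) - c0)
    tau0 = (time[-1] - time[0]) / 3.0

    def model(tt, c, b, tau):
        return c + b * np.exp(-tt / tau)

    # tau is only identifiable up to ~the recording span: without an upper
    # bound a flat trace fits equally well with huge tau and B absorbing
    # the constant, corrupting the amplitude estimate
    tau_max = 10.0 * (time[-1] - time[0])
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[c0, max(b0, 1e-6), min(tau0, tau_max)],
            bounds=([0.0, 0.0, 0.5], [np.inf, np.inf, tau_max]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        resid = float(np.sqrt(np.mean((y - model(t, c0, b0, tau0)) ** 2)))
        raise BleachFitError(f"bleach fit did not converge (rms {resid:.3g})") from err
    C, B, tau = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((y - model(t, C, B, tau)) ** 2)))
    t0 = float(time[0])
    b_at_t0 = B * np.exp(-t0 / tau)
    total = b_at_t0 + C
    amplitude = b_at_t0 / total if total > 0 else 0.0
    plausible = TAU_PLAUSIBLE[0] < tau < TAU_PLAUSIBLE[1]
    return BleachFit(
        amplitude=float(amplitude), tau_b=tau, C=C, B=B, t0=t0,
        rms_residual=resid, cell_ids=[recording.cell_ids[i] for i in idx],
        plausible=plausible,
    )


def correct_bleach(recording: Recording, fit: BleachFit) -> NormalizedRecording:
    """Divide raw traces by the fitted decay (normalized to 1 at the first
    sample), then recompute F0 and dF/F0.  Sets ``corrected``."""
    if not fit.plausible:
        raise BleachFitError(
            f"bleach fit implausible (tau_b = {fit.tau_b:.3g} s); correction disabled"
        )
    d = fit.decay(recording.time)
    if (d <= 0).any():
        raise BleachFitError("fitted decay reaches <= 0 within the recording")
    corrected_raw = Recording(
        time=recording.time,
        traces=recording.traces / d[None, :],
        cell_ids=list(recording.cell_ids),
        schedule=list(recording.schedule),
        metadata=dict(recording.metadata),
    )
    out = compute_dff(corrected_raw)
    out.bleach_fit = fit
    out.corrected = True
    return out


def normalize_recording(recording: Recording, bleach_fit: BleachFit | None = None,
                        amplitude_threshold: float = 0.05) -> NormalizedRecording:
    """One-stop normalization: plain dF/F0, or bleach-corrected dF/F0 when
    a fit is supplied whose bleached fraction exceeds ``amplitude_threshold``
    (correction on near-flat decays is a no-op not worth the extra model)."""
    if bleach_fit is not None and bleach_fit.plausible and \
            bleach_fit.amplitude >= amplitude_threshold:
        return correct_bleach(recording, bleach_fit)
    out = compute_dff(recording)
    out.bleach_fit = bleach_fit
    return out
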