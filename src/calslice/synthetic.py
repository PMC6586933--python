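"""Ground-truth-labelled synthetic slice-perfusion Ca2+ recordings.

Emulates the statistical structure the analysis assumes: 1-2 Hz sampling,
a baseline fluorescence F0 per cell, multiplicative exponential
photobleaching, additive Gaussian noise, a piecewise-linear perfusion
kernel (valve-to-tissue delay ~4 s, full bath exchange ~10 s), and
delayed second-messenger Ca2+ transients (onset ~11-12 s after valve
opening) shaped as a normalized difference of exponentials.  Cells belong
to classes with overlapping tastant-response profiles; movement-artifact
(Ringer-responsive) and spontaneously active cells are included so the
pipeline's exclusion rules are exercised.

Raw fluorescence model per cell::

    F(t) = F0 * (1 - A + A*exp(-t/tau_b)) * (1 + dff(t)) + eps(t) * F0

with ``eps`` i.i.d. Gaussian of SD ``noise_sd`` (dF/F0 scale) and
``dff`` the sum of the cell's transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Recording, StimulusEpoch

__all__ = [
    "TransientParams",
    "HillParams",
    "PerfusionParams",
    "BleachParams",
    "StackGeometry",
    "SynthConfig",
    "GroundTruth",
    "default_config",
    "default_schedule",
    "perfusion_kernel",
    "make_transient",
    "hill_scale",
    "generate_recording",
    "generate_stack",
    "score_against_truth",
]

CELL_CLASSES = (
    "non_responder",
    "atp_only",
    "atp+denatonium",
    "atp+sweetener",
    "atp+both",
    "ringer_artifact",
    "spontaneous",
)

SWEETENERS = frozenset({"sucralose", "saccharin", "acesulfame-K"})


@dataclass(frozen=True)
class TransientParams:
    """Per-compound transient statistics (all times in seconds)."""

    onset_delay_mean: float = 12.0
    onset_delay_sd: float = 1.5
    rise_tau: float = 1.0
    decay_tau: float = 8.0
    peak_mean: float = 1.0
    peak_sd: float = 0.25
    peak_min: float = 0.35  # analyzed responses are unambiguous transients


@dataclass(frozen=True)
class HillParams:
    ec50: float  # mM
    n_hill: float = 1.0


@dataclass(frozen=True)
class PerfusionParams:
    delay: float = 4.0  # s, valve opening -> stimulus reaches the tissue
    full_exchange: float = 10.0  # s, complete change of bath solution


@dataclass(frozen=True)
class BleachParams:
    amplitude: float = 0.1  # fraction A in [0, 1)
    tau: float = 600.0  # s


@dataclass(frozen=True)
class StackGeometry:
    shape: tuple = (64, 64)
    roi_radius: int = 4
    spacing: int = 12  # centre-to-centre grid pitch, pixels
    margin: int = 8
    pixel_noise_sd: float = 0.0  # absolute fluorescence units, per pixel
    background: float = 0.0


@dataclass
class SynthConfig:
    n_cells: int = 400
    sampling_rate: float = 2.0  # Hz
    duration: float = 480.0  # s
    epochs: list = field(default_factory=lambda: default_schedule())
    class_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBABILITIES)
    )
    transient_params: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSIENT_PARAMS)
    )
    hill_params: dict = field(default_factory=lambda: dict(DEFAULT_HILL_PARAMS))
    bleach_params: BleachParams = field(default_factory=BleachParams)
    noise_sd: float = 0.02  # dF/F0 scale
    baseline_f0_mean: float = 100.0
    baseline_f0_sd: float = 20.0
    perfusion: PerfusionParams = field(default_factory=PerfusionParams)
    search_window: float = 60.0  # s after valve opening a response may begin
    spontaneous_events: tuple = (1, 3)  # inclusive range of events per cell
    epoch_gain: dict = field(default_factory=dict)  # epoch_id -> amplitude gain
    seed: int = 0

    def validate(self) -> None:
        probs = self.class_probabilities
        unknown = set(probs) - set(CELL_CLASSES)
        if unknown:
            raise ValueError(f"class_probabilities: unknown classes {sorted(unknown)}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probabilities: sum {total} != 1 within 1e-9")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.bleach_params.tau <= 0:
            raise ValueError("bleach_params.tau must be > 0")
        if not (0 <= self.bleach_params.amplitude < 1):
            raise ValueError("bleach_params.amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.perfusion.delay >= self.perfusion.full_exchange:
            raise ValueError("perfusion delay must be < full-exchange time")
        for comp, tp in self.transient_params.items():
            if tp.rise_tau <= 0 or tp.decay_tau <= 0 or tp.onset_delay_sd < 0:
                raise ValueError(f"transient_params[{comp}]: time constants must be > 0")
        for e in self.epochs:
            if e.valve_open + self.search_window > self.duration:
                raise ValueError(
                    f"duration {self.duration}s does not cover epoch {e.epoch_id} "
                    f"plus its {self.search_window}s search window"
                )

    def transient_for(self, compound: str) -> TransientParams:
        return self.transient_params.get(compound, self.transient_params["default"])


DEFAULT_CLASS_PROBABILITIES = {
    # 95% of cells are artifact-free; 70% of those are ATP-responsive
    # (viable), and of the viable cells 39% respond to denatonium and 26%
    # to the sweetener with an 18% overlap — the responder frequencies the
    # analysis is expected to recover.
    "non_responder": 0.285,
    "atp_only": 0.35245,
    "atp+denatonium": 0.13965,
    "atp+sweetener": 0.0532,
    "atp+both": 0.1197,
    "ringer_artifact": 0.02,
    "spontaneous": 0.03,
}

DEFAULT_TRANSIENT_PARAMS = {
    "default": TransientParams(),
    "ATP": TransientParams(onset_delay_mean=11.0, onset_delay_sd=1.5),
    "denatonium": TransientParams(onset_delay_mean=12.0, onset_delay_sd=1.5),
    "saccharin": TransientParams(onset_delay_mean=12.0, onset_delay_sd=1.5),
    # movement artifacts track the solution switch itself, not a
    # second-messenger cascade: short delay, modest amplitude
    "Ringer": TransientParams(
        onset_delay_mean=5.0, onset_delay_sd=1.0, peak_mean=0.5, peak_sd=0.15,
        peak_min=0.25,
    ),
    "spontaneous": TransientParams(
        onset_delay_mean=0.0, onset_delay_sd=0.0, peak_mean=0.5, peak_sd=0.15,
        peak_min=0.25,
    ),
}

DEFAULT_HILL_PARAMS = {
    "ATP": HillParams(ec50=0.003, n_hill=1.0),  # 30 uM ATP sits near saturation
    "denatonium": HillParams(ec50=1.0, n_hill=1.0),  # 1 mM ~ half of 10 mM
    "saccharin": HillParams(ec50=10.0, n_hill=2.0),  # 5 mM ~ 40% of 10 mM
    "sucralose": HillParams(ec50=5.0, n_hill=1.0),
    "acesulfame-K": HillParams(ec50=5.0, n_hill=1.0),
}


def default_schedule() -> list:
    """ATP viability control, Ringer vehicle control, then two tastants."""
    return [
        StimulusEpoch(1, "ATP", 0.03, 30.0, 10.0, "viability_control"),
        StimulusEpoch(2, "Ringer", 0.0, 150.0, 10.0, "vehicle_control"),
        StimulusEpoch(3, "denatonium", 5.0, 270.0, 10.0, "test"),
        StimulusEpoch(4, "saccharin", 10.0, 390.0, 10.0, "test"),
    ]


def default_config(n_cells: int = 400, seed: int = 0, **overrides) -> SynthConfig:
    cfg = SynthConfig(n_cells=n_cells, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """Recovery-test oracle: true class, transients and constants per cell."""

    classes: dict  # cell_id -> class label
    events: pd.DataFrame  # cell_id, class, epoch_id, compound, true_onset_s, true_peak_dff
    f0: dict  # cell_id -> true baseline
    bleach: dict  # cell_id -> (A, tau_b)

    def to_frame(self) -> pd.DataFrame:
        if len(self.events):
            return self.events.copy()
        return pd.DataFrame(
            columns=["cell_id", "class", "epoch_id", "compound", "true_onset_s", "true_peak_dff"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# primitives


def perfusion_kernel(t_since_valve, perfusion: PerfusionParams):
    """Stimulus concentration fraction at the tissue.

    0 before the valve-to-tissue delay, 1 at and after the full-exchange
    time, linear in between.  Negative times are valid (pre-stimulus) and
    return 0.
    """
    if perfusion.delay >= perfusion.full_exchange:
        raise ValueError("perfusion delay must be < full-exchange time")
    t = np.asarray(t_since_valve, dtype=float)
    frac = np.clip(
        (t - perfusion.delay) / (perfusion.full_exchange - perfusion.delay), 0.0, 1.0
    )
    return float(frac) if np.isscalar(t_since_valve) else frac


def make_transient(onset, rise_tau, decay_tau, peak, time_axis):
    """Difference-of-exponentials Ca2+ transient sampled on ``time_axis``.

    Zero before ``onset``; the shape is rescaled so its maximum over the
    sampled axis equals ``peak`` exactly (so the ground-truth peak is
    recoverable from the sampled trace).
    """
    if rise_tau >= decay_tau:
        raise ValueError("rise_tau must be < decay_tau")
    if rise_tau <= 0:
        raise ValueError("rise_tau must be > 0")
    if peak < 0:
        raise ValueError("peak must be >= 0")
    t = np.asarray(time_axis, dtype=float)
    s = t - onset
    out = np.zeros_like(t)
    pos = s > 0
    out[pos] = np.exp(-s[pos] / decay_tau) - np.exp(-s[pos] / rise_tau)
    m = out.max()
    if m > 0 and peak > 0:
        out *= peak / m
    else:
        out[:] = 0.0
    return out


def transient_argmax_time(rise_tau: float, decay_tau: float) -> float:
    """Closed-form time-to-peak of the difference of exponentials."""
    return np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def hill_scale(concentration: float, ec50: float, n_hill: float) -> float:
    """Hill occupancy c^n / (c^n + EC50^n), in (0, 1)."""
    if concentration <= 0 or ec50 <= 0 or n_hill <= 0:
        raise ValueError("hill_scale: all arguments must be > 0")
    cn = concentration**n_hill
    return float(cn / (cn + ec50**n_hill))


# ---------------------------------------------------------------------------
# recording generation


def _responds_to(cls: str, compound: str) -> bool:
    if compound == "ATP":
        return cls in ("atp_only", "atp+denatonium", "atp+sweetener", "atp+both", "spontaneous")
    if compound == "denatonium":
        return cls in ("atp+denatonium", "atp+both")
    if compound in SWEETENERS:
        return cls in ("atp+sweetener", "atp+both")
    return False


def _truncated_normal(rng, mean, sd, lower):
    """Rejection-sampled Gaussian truncated below at ``lower``."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    return lower


def generate_recording(config: SynthConfig):
    """Simulate one slice experiment; returns (Recording, GroundTruth).

    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate
    time = np.arange(0.0, config.duration, dt)
    n = config.n_cells
    labels = list(CELL_CLASSES)
    probs = np.array([config.class_probabilities.get(c, 0.0) for c in labels])
    classes = rng.choice(labels, size=n, p=probs)
    cell_ids = [f"cell_{i+1:04d}" for i in range(n)]

    A, tau_b = config.bleach_params.amplitude, config.bleach_params.tau
    bleach_curve = 1.0 - A + A * np.exp(-time / tau_b)
    epochs = sorted(config.epochs, key=lambda e: e.valve_open)
    windows = [(e.valve_open, e.valve_open + config.search_window) for e in epochs]

    traces = np.empty((n, time.size))
    events = []
    f0_map, bleach_map = {}, {}
    for i, (cid, cls) in enumerate(zip(cell_ids, classes)):
        f0 = max(rng.normal(config.baseline_f0_mean, config.baseline_f0_sd), 1.0)
        f0_map[cid] = f0
        bleach_map[cid] = (A, tau_b)
        dff = np.zeros_like(time)

        for e in epochs:
            is_ringer_epoch = e.compound.lower() == "ringer"
            if cls == "ringer_artifact":
                stimulated = is_ringer_epoch
            else:
                stimulated = (not is_ringer_epoch) and _responds_to(cls, e.compound)
            if not stimulated:
                continue
            tp = config.transient_for("Ringer" if is_ringer_epoch else e.compound)
            delay = _truncated_normal(
                rng, tp.onset_delay_mean, tp.onset_delay_sd, config.perfusion.delay
            )
            onset = e.valve_open + delay
            peak = _truncated_normal(rng, tp.peak_mean, tp.peak_sd, tp.peak_min)
            if not is_ringer_epoch and e.compound in config.hill_params:
                hp = config.hill_params[e.compound]
                peak *= hill_scale(e.concentration, hp.ec50, hp.n_hill)
            peak *= config.epoch_gain.get(e.epoch_id, 1.0)
            tr = make_transient(onset, tp.rise_tau, tp.decay_tau, peak, time)
            dff += tr
            events.append(
                dict(cell_id=cid, cls=cls, epoch_id=e.epoch_id, compound=e.compound,
                     true_onset_s=onset, true_peak_dff=float(tr.max()))
            )

        if cls == "spontaneous":
            lo, hi = config.spontaneous_events
            tp = config.transient_for("spontaneous")
            for _ in range(int(rng.integers(lo, hi + 1))):
                onset = _random_gap_time(rng, time, windows)
                peak = _truncated_normal(rng, tp.peak_mean, tp.peak_sd, tp.peak_min)
                tr = make_transient(onset, tp.rise_tau, tp.decay_tau, peak, time)
                dff += tr
                events.append(
                    dict(cell_id=cid, cls=cls, epoch_id=None, compound="spontaneous",
                         true_onset_s=onset, true_peak_dff=float(tr.max()))
                )

        noise = rng.normal(0.0, config.noise_sd, size=time.size) if config.noise_sd else 0.0
        traces[i] = f0 * bleach_curve * (1.0 + dff) + noise * f0

    rec = Recording(
        time=time,
        traces=traces,
        cell_ids=cell_ids,
        schedule=list(epochs),
        metadata={"sampling_rate": config.sampling_rate, "seed": config.seed},
    )
    ev = pd.DataFrame(
        events,
        columns=["cell_id", "cls", "epoch_id", "compound", "true_onset_s", "true_peak_dff"],
    ).rename(columns={"cls": "class"})
    truth = GroundTruth(
        classes=dict(zip(cell_ids, classes)), events=ev, f0=f0_map, bleach=bleach_map
    )
    return rec, truth


def _random_gap_time(rng, time, windows, margin: float = 25.0):
    """Uniform time outside all stimulus search windows and clear of the
    recording edges (so the transient fits inside the trace)."""
    t0, t1 = time[0] + 5.0, time[-1] - margin
    for _ in range(1000):
        t = rng.uniform(t0, t1)
        if all(not (lo <= t <= hi) for lo, hi in windows):
            return t
    return t0


# ---------------------------------------------------------------------------
# image stacks


def generate_stack(recording: Recording, geometry: StackGeometry = StackGeometry(),
                   seed: int = 0):
    """Render a recording as a multi-page stack plus an ROI label mask.

    ROIs are disks on a grid; mask labels are 1..n_cells in cell order and
    background is 0.  Per-pixel Gaussian noise of SD ``pixel_noise_sd``
    (absolute units) is added independently, so each ROI's pixel-mean
    series matches its trace within SE = pixel_noise_sd / sqrt(n_pixels).
    """
    h, w = geometry.shape
    r, pitch, m = geometry.roi_radius, geometry.spacing, geometry.margin
    if pitch < 2 * r + 1:
        raise ValueError("geometry: ROI spacing implies overlapping ROIs")
    xs = list(range(m, w - m + 1, pitch))
    ys = list(range(m, h - m + 1, pitch))
    centres = [(y, x) for y in ys for x in xs]
    if len(centres) < recording.n_cells:
        raise ValueError(
            f"geometry: frame fits {len(centres)} ROIs but recording has "
            f"{recording.n_cells} cells"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.uint16)
    for lab, (cy, cx) in enumerate(centres[: recording.n_cells], start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if mask[disk].any():
            raise ValueError("geometry: overlapping ROIs")
        mask[disk] = lab
    rng = np.random.default_rng(seed)
    n_frames = recording.n_time
    stack = np.full((n_frames, h, w), float(geometry.background))
    for lab in range(1, recording.n_cells + 1):
        sel = mask == lab
        stack[:, sel] = recording.traces[lab - 1][:, None]
    if geometry.pixel_noise_sd > 0:
        stack += rng.normal(0.0, geometry.pixel_noise_sd, size=stack.shape)
    return stack, mask


# ---------------------------------------------------------------------------
# recovery scoring


def score_against_truth(calls, truth: GroundTruth, roles=("viability_control", "test")):
    """Per-(cell, epoch) confusion of response calls against ground truth.

    Detection is scored on cells whose true class is not an artifact class
    (ringer_artifact / spontaneous cells are the exclusion rules' job and
    are reported separately as flag rates).
    """
    truth_pos = {
        (r.cell_id, int(r.epoch_id))
        for r in truth.events.itertuples()
        if r.epoch_id is not None and not pd.isna(r.epoch_id)
    }
    artifact = {c for c, k in truth.classes.items() if k in ("ringer_artifact", "spontaneous")}
    tp = fp = fn = tn = 0
    for c in calls:
        if c.cell_id in artifact:
            continue
        if c.compound.lower() == "ringer":
            continue
        positive = (c.cell_id, c.epoch_id) in truth_pos
        if c.responsive and positive:
            tp += 1
        elif c.responsive and not positive:
            fp += 1
        elif not c.responsive and positive:
            fn += 1
        else:
            tn += 1
    flagged = {}
    for c in calls:
        flagged.setdefault(c.cell_id, set()).add(c.exclusion_reason)
    ringer_cells = [c for c, k in truth.classes.items() if k == "ringer_artifact"]
    spont_cells = [c for c, k in truth.classes.items() if k == "spontaneous"]
    ringer_rate = (
        np.mean(["ringer_responsive" in flagged.get(c, set()) for c in ringer_cells])
        if ringer_cells else np.nan
    )
    spont_rate = (
        np.mean(["spontaneous_activity" in flagged.get(c, set()) for c in spont_cells])
        if spont_cells else np.nan
    )
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ringer_flag_rate": float(ringer_rate),
        "spontaneous_flag_rate": float(spont_rate),
    }
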