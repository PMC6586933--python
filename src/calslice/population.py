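"""Population-level aggregation of response calls.

Responder frequencies are conditioned on the viability control (only
ATP-responsive cells enter tastant analysis), overlap (Venn) profiles are
restricted to cells responding to at least one of the compared compounds,
dose-response peaks are normalized within-cell to the reference
concentration, and repeated-stimulation pharmacology is normalized to the
first stimulation's peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseProfile",
    "FrequencyTable",
    "DoseResponse",
    "round_half_up",
    "build_profiles",
    "frequency_table",
    "venn_counts",
    "retention_counts",
    "dose_response",
    "normalize_to_first",
    "heatmap_matrix",
    "plot_heatmap",
]


def round_half_up(x: float) -> int:
    """Report-table rounding convention (0.5 always rounds up)."""
    return int(math.floor(x + 0.5))


@dataclass
class ResponseProfile:
    cell_id: str
    atp_responsive: bool
    responded_to: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.responded_to = frozenset(self.responded_to)
        if self.responded_to and not self.atp_responsive:
            raise ValueError(
                f"cell {self.cell_id}: tastant responses recorded for a "
                "non-viable (ATP-unresponsive) cell"
            )

    @property
    def profile_key(self) -> str:
        return "+".join(sorted(self.responded_to)) if self.responded_to else ""


@dataclass
class FrequencyTable:
    denominator_label: str
    rows: pd.DataFrame  # label, count, denominator, percent

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


@dataclass
class DoseResponse:
    compound: str
    reference_concentration: float
    points: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: concentration_mM, mean_normalized_peak, sem, n


def build_profiles(calls, viability_compound: str = "ATP"):
    """Per-cell response profiles conditioned on the viability control.

    Excluded cells (any exclusion flag) are dropped; cells with no
    viability-compound call are dropped with a warning entry.  Returns
    (profiles, dropped) where dropped maps cell_id -> reason.
    """
    by_cell: dict[str, list] = {}
    for c in calls:
        by_cell.setdefault(c.cell_id, []).append(c)

    profiles, dropped = [], {}
    for cid, cs in by_cell.items():
        reasons = {c.exclusion_reason for c in cs} - {"none"}
        if reasons:
            dropped[cid] = sorted(reasons)[0]
            continue
        via = [c for c in cs if c.compound == viability_compound]
        if not via:
            dropped[cid] = "missing_viability_epoch"
            continue
        atp = any(c.responsive for c in via)
        responded = {
            c.compound for c in cs
            if c.responsive and c.compound != viability_compound
            and c.compound.lower() != "ringer"
        }
        profiles.append(
            ResponseProfile(cell_id=cid, atp_responsive=atp,
                            responded_to=responded if atp else frozenset())
        )
    return profiles, dropped


def frequency_table(profiles, compounds, denominator_label: str = "ATP-responsive cells"):
    """Responder counts per compound over the ATP-responsive denominator,
    plus a profile partition of the cells responding to >= 1 listed
    compound (the overlap-figure convention)."""
    viable = [p for p in profiles if p.atp_responsive]
    denom = len(viable)
    if denom == 0:
        raise ValueError("frequency_table: empty denominator (no viable cells)")
    rows = []
    for comp in compounds:
        count = sum(comp in p.responded_to for p in viable)
        rows.append(dict(label=comp, kind="compound", count=count,
                         denominator=denom, percent=100.0 * count / denom))
    responders = [p for p in viable if p.responded_to & set(compounds)]
    n_resp = len(responders)
    keys = sorted({
        "+".join(sorted(p.responded_to & set(compounds))) for p in responders
    })
    for key in keys:
        count = sum(
            "+".join(sorted(p.responded_to & set(compounds))) == key
            for p in responders
        )
        rows.append(dict(label=key, kind="profile", count=count,
                         denominator=n_resp,
                         percent=100.0 * count / n_resp if n_resp else 0.0))
    df = pd.DataFrame(rows, columns=["label", "kind", "count", "denominator", "percent"])
    return FrequencyTable(denominator_label=denominator_label, rows=df)


def venn_counts(profiles, compound_a: str, compound_b: str):
    """(only_a, only_b, both, total) over cells responding to >= 1 of the
    two compounds; total = only_a + only_b + both."""
    only_a = only_b = both = 0
    for p in profiles:
        if not p.atp_responsive:
            continue
        a = compound_a in p.responded_to
        b = compound_b in p.responded_to
        if a and b:
            both += 1
        elif a:
            only_a += 1
        elif b:
            only_b += 1
    return only_a, only_b, both, only_a + only_b + both


def retention_counts(calls_before, calls_after, compound: str):
    """(n_retained, n_total): of the cells responsive to ``compound``
    before a treatment, how many are still responsive after it.  The two
    phases must cover the same cells (matched by cell_id)."""
    def _resp(calls):
        out = {}
        for c in calls:
            if c.compound == compound:
                out[c.cell_id] = out.get(c.cell_id, False) or bool(c.responsive)
        return out

    before, after = _resp(calls_before), _resp(calls_after)
    if set(before) != set(after):
        missing = set(before) ^ set(after)
        raise ValueError(f"retention_counts: cell-id mismatch between phases: {sorted(missing)[:5]}")
    total = [cid for cid, r in before.items() if r]
    retained = [cid for cid in total if after[cid]]
    return len(retained), len(total)


def dose_response(calls, compound: str, reference_concentration: float,
                  concentrations: dict):
    """Within-cell normalization of peak dF/F0 to the reference dose.

    ``concentrations`` maps epoch_id -> concentration (mM) for the
    compound's epochs.  Cells lacking a responsive call at the reference
    concentration are dropped (returned in the second element).
    """
    per_cell: dict[str, dict[float, float]] = {}
    for c in calls:
        if c.compound != compound or c.epoch_id not in concentrations:
            continue
        if c.peak_dff is None:
            continue
        per_cell.setdefault(c.cell_id, {})[concentrations[c.epoch_id]] = (
            float(c.peak_dff), bool(c.responsive))
    dropped = []
    norm_rows = []
    for cid, peaks in per_cell.items():
        ref = peaks.get(reference_concentration)
        if ref is None or not ref[1]:
            dropped.append(cid)
            continue
        for conc, (peak, _) in peaks.items():
            norm_rows.append(dict(cell_id=cid, concentration_mM=conc,
                                  normalized_peak=peak / ref[0]))
    df = pd.DataFrame(norm_rows, columns=["cell_id", "concentration_mM", "normalized_peak"])
    if len(df):
        g = df.groupby("concentration_mM")["normalized_peak"]
        points = pd.DataFrame({
            "concentration_mM": g.mean().index,
            "mean_normalized_peak": g.mean().to_numpy(),
            "sem": (g.std(ddof=1) / np.sqrt(g.count())).to_numpy(),
            "n": g.count().to_numpy(),
        }).reset_index(drop=True)
    else:
        points = pd.DataFrame(
            columns=["concentration_mM", "mean_normalized_peak", "sem", "n"])
    return DoseResponse(compound=compound,
                        reference_concentration=reference_concentration,
                        points=points), dropped


def normalize_to_first(calls, compound: str):
    """Repeated-stimulation peaks divided by each cell's first-stimulation
    peak (so the first value is exactly 1).  Cells whose first stimulation
    was not responsive are dropped.

    Returns (DataFrame with cell_id, stimulation_index, normalized_peak;
    dropped cell ids).
    """
    per_cell: dict[str, list] = {}
    for c in calls:
        if c.compound == compound and c.peak_dff is not None:
            per_cell.setdefault(c.cell_id, []).append(c)
    rows, dropped = [], []
    for cid, cs in per_cell.items():
        cs = sorted(cs, key=lambda c: c.epoch_id)
        if len(cs) < 2 or not cs[0].responsive:
            dropped.append(cid)
            continue
        first = float(cs[0].peak_dff)
        for k, c in enumerate(cs, start=1):
            rows.append(dict(cell_id=cid, stimulation_index=k,
                             normalized_peak=float(c.peak_dff) / first))
    return (pd.DataFrame(rows, columns=["cell_id", "stimulation_index", "normalized_peak"]),
            dropped)


def heatmap_matrix(normalized, profiles, epoch=None):
    """dF/F0 matrix with rows grouped by response profile.

    Rows are cells sorted by profile_key, then by peak amplitude
    descending (peak over the given epoch's search window, or the whole
    trace).  Returns (matrix, row_cell_ids, group_boundaries) where
    boundaries are row indices at which a new profile group starts
    (excluding 0).
    """
    prof_by_cell = {p.cell_id: p for p in profiles}
    cells = [c for c in normalized.cell_ids if c in prof_by_cell]
    if not cells:
        return np.empty((0, normalized.time.size)), [], []

    if epoch is not None:
        sel = (normalized.time >= epoch.valve_open) & \
              (normalized.time <= epoch.valve_open + epoch.duration + 60.0)
    else:
        sel = np.ones_like(normalized.time, dtype=bool)

    def sort_key(cid):
        tr = normalized.trace(cid)
        peak = float(np.nanmax(tr[sel])) if sel.any() else 0.0
        return (prof_by_cell[cid].profile_key, -peak, cid)

    ordered = sorted(cells, key=sort_key)
    matrix = np.vstack([normalized.trace(c) for c in ordered])
    boundaries = [
        i for i in range(1, len(ordered))
        if prof_by_cell[ordered[i]].profile_key != prof_by_cell[ordered[i - 1]].profile_key
    ]
    return matrix, ordered, boundaries


def plot_heatmap(matrix, boundaries, time=None, path=None, cmap="viridis"):
    """Render the profile-grouped dF/F0 heat map; thin black lines divide
    cells with different response profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    extent = None
    if time is not None and len(time):
        extent = (time[0], time[-1], matrix.shape[0], 0)
    im = ax.imshow(matrix, aspect="auto", cmap=cmap, extent=extent,
                   interpolation="nearest")
    for b in boundaries:
        ax.axhline(b, color="black", linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    fig.colorbar(im, ax=ax, label=r"$\Delta F/F_0$")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
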