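"""End-to-end analysis: normalization, bleach correction, response calling
and population summaries in one call.

Bleach correction is two-pass and self-contained: responses are first
called on uncorrected dF/F0, the exponential decay is then fitted on the
cells with no responsive call and no exclusion flag (the non-responding
cells), and — when the fitted bleached fraction exceeds a threshold —
traces are re-normalized against the fitted decay and re-called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .calling import CallParams, call_recording, onset_delay_summary
from .population import (
    build_profiles,
    frequency_table,
    heatmap_matrix,
    venn_counts,
)
from .preprocessing import (
    BleachFit,
    BleachFitError,
    NormalizedRecording,
    compute_dff,
    normalize_recording,
)

__all__ = ["AnalysisResult", "analyze_recording", "write_analysis"]

#: fitted bleached fraction above which auto mode applies the correction
BLEACH_AMPLITUDE_THRESHOLD = 0.05


@dataclass
class AnalysisResult:
    normalized: NormalizedRecording
    calls: list
    profiles: list
    dropped: dict
    bleach_fit: BleachFit | None = None
    bleach_applied: bool = False
    first_pass_calls: list = field(default_factory=list)

    def summary(self, compounds=None) -> dict:
        sched = self.normalized.schedule
        if compounds is None:
            compounds = sorted({
                e.compound for e in sched
                if e.role == "test" and e.compound.lower() != "ringer"
            })
        viable = [p for p in self.profiles if p.atp_responsive]
        out = {
            "n_cells": len(self.normalized.cell_ids),
            "n_analyzed": len(self.profiles),
            "n_excluded": len(self.dropped),
            "n_atp_responsive": len(viable),
            "bleach_applied": self.bleach_applied,
        }
        if self.bleach_fit is not None:
            out["bleach_fit"] = {
                "amplitude": self.bleach_fit.amplitude,
                "tau_b_s": self.bleach_fit.tau_b,
                "rms_residual": self.bleach_fit.rms_residual,
                "n_cells": len(self.bleach_fit.cell_ids),
            }
        if self.profiles and viable:
            out["frequencies"] = frequency_table(self.profiles, compounds).rows.to_dict(
                orient="records"
            )
        delays = {}
        for comp in list(compounds) + ["ATP"]:
            mean, sem, n = onset_delay_summary(self.calls, comp)
            if n:
                delays[comp] = {"mean_s": mean, "sem_s": sem if n > 1 else None, "n": n}
        out["onset_delays"] = delays
        return out


def _first_pass_non_responders(calls) -> list:
    by_cell: dict[str, list] = {}
    for c in calls:
        by_cell.setdefault(c.cell_id, []).append(c)
    return [
        cid for cid, cs in by_cell.items()
        if not any(c.responsive for c in cs)
        and all(c.exclusion_reason in ("none",) for c in cs)
    ]


def analyze_recording(recording: cio.Recording, params: CallParams = CallParams(),
                      bleach_correction: str = "auto",
                      bleach_threshold: float = BLEACH_AMPLITUDE_THRESHOLD,
                      viability_compound: str = "ATP") -> AnalysisResult:
    """Run the full pipeline on one recording.

    ``bleach_correction``: ``auto`` (two-pass, applied when the fitted
    bleached fraction exceeds ``bleach_threshold``), ``off``, or a
    pre-computed :class:`BleachFit` instance to apply unconditionally.
    """
    from .preprocessing import fit_bleach, correct_bleach

    norm = compute_dff(recording)
    first_calls = call_recording(norm, params)
    fit = None
    applied = False

    if isinstance(bleach_correction, BleachFit):
        fit = bleach_correction
        norm2 = correct_bleach(recording, fit)
        calls = call_recording(norm2, params)
        norm, applied = norm2, True
    elif bleach_correction == "auto":
        non_resp = _first_pass_non_responders(first_calls)
        try:
            fit = fit_bleach(recording, non_resp, search_window=params.search_window)
        except BleachFitError:
            fit = None
        if fit is not None and fit.plausible and fit.amplitude >= bleach_threshold:
            norm2 = normalize_recording(recording, fit, bleach_threshold)
            calls = call_recording(norm2, params)
            norm, applied = norm2, norm2.corrected
        else:
            calls = first_calls
            norm.bleach_fit = fit
    elif bleach_correction == "off":
        calls = first_calls
    else:
        raise ValueError(f"unknown bleach_correction mode {bleach_correction!r}")

    profiles, dropped = build_profiles(calls, viability_compound)
    return AnalysisResult(
        normalized=norm, calls=calls, profiles=profiles, dropped=dropped,
        bleach_fit=fit, bleach_applied=applied, first_pass_calls=first_calls,
    )


def write_analysis(result: AnalysisResult, out_dir, compounds=None,
                   render_heatmap: bool = False) -> dict:
    """Write calls.csv, frequencies.csv, venn.csv, heatmap.csv and
    summary.json to ``out_dir``; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = result.normalized.schedule
    if compounds is None:
        compounds = sorted({
            e.compound for e in sched
            if e.role == "test" and e.compound.lower() != "ringer"
        })

    cio.write_calls(result.calls, out / "calls.csv")

    summary = result.summary(compounds)
    viable = [p for p in result.profiles if p.atp_responsive]
    if viable:
        ft = frequency_table(result.profiles, compounds)
        ft.rows.to_csv(out / "frequencies.csv", index=False)
        venn_rows = []
        for i, a in enumerate(compounds):
            for b in compounds[i + 1:]:
                oa, ob, both, total = venn_counts(result.profiles, a, b)
                venn_rows.append(dict(compound_a=a, compound_b=b, only_a=oa,
                                      only_b=ob, both=both, total=total))
        pd.DataFrame(
            venn_rows,
            columns=["compound_a", "compound_b", "only_a", "only_b", "both", "total"],
        ).to_csv(out / "venn.csv", index=False)
        summary["venn"] = venn_rows

    matrix, row_ids, boundaries = heatmap_matrix(result.normalized, result.profiles)
    hm = pd.DataFrame(matrix, index=pd.Index(row_ids, name="cell_id"),
                      columns=[f"{t:.3f}" for t in result.normalized.time])
    hm.to_csv(out / "heatmap.csv")
    summary["heatmap_group_boundaries"] = boundaries
    if render_heatmap and matrix.size:
        from .population import plot_heatmap
        plot_heatmap(matrix, boundaries, time=result.normalized.time,
                     path=out / "heatmap.png")

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
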