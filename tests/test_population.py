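import numpy as np
import pytest

from calslice.calling import ResponseCall
from calslice.population import (
    ResponseProfile,
    build_profiles,
    dose_response,
    frequency_table,
    heatmap_matrix,
    normalize_to_first,
    retention_counts,
    round_half_up,
    venn_counts,
)


def call(cid, epoch_id, compound, responsive, peak=0.5, exclusion="none"):
    return ResponseCall(
        cell_id=cid, epoch_id=epoch_id, compound=compound,
        responsive=responsive and exclusion == "none",
        peak_dff=peak, exclusion_reason=exclusion,
    )


def profiles_from_counts(spec):
    """[(n, atp_responsive, responded_to), ...] -> profile list."""
    out, k = [], 0
    for n, atp, responded in spec:
        for _ in range(n):
            out.append(ResponseProfile(f"c{k}", atp, frozenset(responded)))
            k += 1
    return out


class TestBuildProfiles:
    def test_atp_only_cell_has_empty_profile(self):
        calls = [call("c1", 1, "ATP", True), call("c1", 2, "Ringer", False),
                 call("c1", 3, "denatonium", False)]
        profiles, dropped = build_profiles(calls)
        assert not dropped
        (p,) = profiles
        assert p.atp_responsive and p.profile_key == ""

    def test_profile_key_is_sorted(self):
        calls = [call("c1", 1, "ATP", True),
                 call("c1", 4, "saccharin", True),
                 call("c1", 3, "denatonium", True)]
        (p,), _ = build_profiles(calls)
        assert p.profile_key == "denatonium+saccharin"

    def test_excluded_cells_dropped(self):
        calls = [call("c1", 1, "ATP", True, exclusion="ringer_responsive"),
                 call("c2", 1, "ATP", True)]
        profiles, dropped = build_profiles(calls)
        assert dropped == {"c1": "ringer_responsive"}
        assert [p.cell_id for p in profiles] == ["c2"]

    def test_missing_viability_epoch_dropped_with_reason(self):
        calls = [call("c1", 3, "denatonium", True)]
        profiles, dropped = build_profiles(calls)
        assert profiles == []
        assert dropped == {"c1": "missing_viability_epoch"}

    def test_configured_overlap_fraction_recovered(self):
        # 18% both-responders among viable cells, recovered within the
        # binomial 95% CI at n = 300
        from calslice import default_config, generate_recording
        from calslice.pipeline import analyze_recording

        cfg = default_config(n_cells=300, seed=31)
        rec, truth = generate_recording(cfg)
        res = analyze_recording(rec, bleach_correction="off")
        both = [p for p in res.profiles if p.atp_responsive
                and {"denatonium", "saccharin"} <= p.responded_to]
        viable = [p for p in res.profiles if p.atp_responsive]
        frac = len(both) / len(viable)
        ci = 1.96 * np.sqrt(0.18 * 0.82 / len(viable))
        assert abs(frac - 0.18) <= ci


class TestFrequencyTable:
    def test_reproduces_printed_percentages(self):
        profiles = profiles_from_counts([
            (118, True, {"denatonium"}), (185, True, set()), (127, False, set()),
        ])
        ft = frequency_table(profiles, ["denatonium"])
        row = ft.rows[(ft.rows.label == "denatonium") & (ft.rows.kind == "compound")]
        assert int(row["count"].iloc[0]) == 118
        assert int(row["denominator"].iloc[0]) == 303
        assert row["percent"].iloc[0] == pytest.approx(100 * 118 / 303)
        assert round_half_up(row["percent"].iloc[0]) == 39

    def test_zero_responders_gives_zero_percent(self):
        profiles = profiles_from_counts([(10, True, set())])
        ft = frequency_table(profiles, ["denatonium"])
        assert ft.rows.percent.iloc[0] == 0.0

    def test_profile_rows_partition_the_responders(self):
        profiles = profiles_from_counts([
            (5, True, {"denatonium"}), (3, True, {"saccharin"}),
            (2, True, {"denatonium", "saccharin"}), (4, True, set()),
        ])
        ft = frequency_table(profiles, ["denatonium", "saccharin"])
        prof = ft.rows[ft.rows.kind == "profile"]
        assert prof["count"].sum() == 10  # cells responding to >= 1 compound
        assert set(prof.denominator) == {10}

    def test_empty_denominator_is_an_error(self):
        profiles = profiles_from_counts([(5, False, set())])
        with pytest.raises(ValueError, match="denominator"):
            frequency_table(profiles, ["denatonium"])


class TestVennCounts:
    def test_denatonium_sucralose_published_counts(self):
        profiles = profiles_from_counts([
            (99, True, {"denatonium"}), (1, True, {"sucralose"}),
            (8, True, {"denatonium", "sucralose"}), (50, True, set()),
        ])
        assert venn_counts(profiles, "denatonium", "sucralose") == (99, 1, 8, 108)

    def test_denatonium_saccharin_published_counts(self):
        profiles = profiles_from_counts([
            (9, True, {"denatonium"}), (14, True, {"saccharin"}),
            (5, True, {"denatonium", "saccharin"}),
        ])
        assert venn_counts(profiles, "denatonium", "saccharin") == (9, 14, 5, 28)

    def test_no_responders(self):
        profiles = profiles_from_counts([(10, True, set())])
        assert venn_counts(profiles, "denatonium", "sucralose") == (0, 0, 0, 0)

    def test_components_sum_to_total(self, rng):
        for _ in range(20):
            spec = [(int(rng.integers(0, 20)), True, s)
                    for s in ({"a"}, {"b"}, {"a", "b"}, set())]
            profiles = profiles_from_counts(spec)
            oa, ob, both, total = venn_counts(profiles, "a", "b")
            assert oa + ob + both == total


class TestRetention:
    def _phase(self, n_resp, n_total, epoch_id):
        calls = []
        for i in range(n_total):
            calls.append(call(f"c{i}", epoch_id, "saccharin", i < n_resp))
        return calls

    def test_all_retained(self):
        before, after = self._phase(5, 8, 1), self._phase(5, 8, 2)
        assert retention_counts(before, after, "saccharin") == (5, 5)

    def test_published_carbenoxolone_case(self):
        before, after = self._phase(71, 80, 1), self._phase(57, 80, 2)
        assert retention_counts(before, after, "saccharin") == (57, 71)

    def test_swapping_phases_changes_denominator(self):
        before, after = self._phase(71, 80, 1), self._phase(57, 80, 2)
        assert retention_counts(after, before, "saccharin") == (57, 57)

    def test_cell_mismatch_raises(self):
        before = self._phase(3, 4, 1)
        after = self._phase(3, 5, 2)
        with pytest.raises(ValueError, match="mismatch"):
            retention_counts(before, after, "saccharin")


class TestDoseResponse:
    def _calls(self, peaks_by_cell, concs={1: 1.0, 2: 5.0, 3: 10.0}):
        calls = []
        for cid, peaks in peaks_by_cell.items():
            for eid, peak in peaks.items():
                calls.append(call(cid, eid, "denatonium", peak is not None,
                                  peak=peak or 0.0))
        return calls, concs

    def test_reference_normalizes_to_one(self):
        calls, concs = self._calls({"c1": {3: 0.4}})
        dr, dropped = dose_response(calls, "denatonium", 10.0, concs)
        assert not dropped
        assert dr.points.mean_normalized_peak.iloc[0] == pytest.approx(1.0)

    def test_half_peak_at_low_dose(self):
        calls, concs = self._calls({"c1": {1: 0.2, 3: 0.4}})
        dr, _ = dose_response(calls, "denatonium", 10.0, concs)
        by_conc = dr.points.set_index("concentration_mM").mean_normalized_peak
        assert by_conc[1.0] == pytest.approx(0.5)
        assert by_conc[10.0] == pytest.approx(1.0)

    def test_cell_without_reference_response_dropped(self):
        calls, concs = self._calls({"c1": {1: 0.2}, "c2": {1: 0.1, 3: 0.4}})
        dr, dropped = dose_response(calls, "denatonium", 10.0, concs)
        assert dropped == ["c1"]
        assert set(dr.points.concentration_mM) == {1.0, 10.0}


class TestNormalizeToFirst:
    def _repeat_calls(self, peaks, cid="c1"):
        return [call(cid, i + 1, "denatonium", True, peak=p)
                for i, p in enumerate(peaks)]

    def test_equal_peaks(self):
        df, dropped = normalize_to_first(self._repeat_calls([0.4, 0.4]), "denatonium")
        assert list(df.normalized_peak) == [1.0, 1.0]

    def test_blocker_scaling(self):
        df, _ = normalize_to_first(self._repeat_calls([0.4, 0.1]), "denatonium")
        assert list(df.normalized_peak) == [1.0, 0.25]

    def test_first_element_is_exactly_one_per_cell(self, rng):
        calls = []
        for i in range(10):
            peaks = rng.uniform(0.1, 1.0, size=3)
            calls += self._repeat_calls(peaks, cid=f"c{i}")
        df, _ = normalize_to_first(calls, "denatonium")
        firsts = df[df.stimulation_index == 1].normalized_peak
        assert (firsts == 1.0).all()

    def test_nonresponsive_first_stimulation_dropped(self):
        calls = [call("c1", 1, "denatonium", False, peak=0.01),
                 call("c1", 2, "denatonium", True, peak=0.3)]
        df, dropped = normalize_to_first(calls, "denatonium")
        assert dropped == ["c1"] and df.empty

    def test_blocker_simulation_detected_by_u_test(self):
        # second-stimulation amplitude scaled to 5%: group median near 0.05
        # and clearly separated from controls
        from calslice import default_config, generate_recording
        from calslice.calling import CallParams, call_recording
        from calslice.io import StimulusEpoch
        from calslice.preprocessing import compute_dff
        from calslice.stats import mann_whitney_u

        epochs = [
            StimulusEpoch(1, "ATP", 0.03, 30.0, 10.0, "viability_control"),
            StimulusEpoch(2, "Ringer", 0.0, 150.0, 10.0, "vehicle_control"),
            StimulusEpoch(3, "denatonium", 5.0, 270.0, 10.0, "test"),
            StimulusEpoch(4, "denatonium", 5.0, 390.0, 10.0, "test"),
        ]

        def second_peaks(gain, seed):
            cfg = default_config(
                n_cells=10, seed=seed, epochs=epochs,
                class_probabilities={"atp+denatonium": 1.0},
                epoch_gain={4: gain},
            )
            rec, _ = generate_recording(cfg)
            calls = call_recording(compute_dff(rec),
                                   CallParams(spontaneous_policy=True))
            df, _ = normalize_to_first(calls, "denatonium")
            return df[df.stimulation_index == 2].normalized_peak.to_numpy()

        blocked = second_peaks(0.05, seed=41)
        control = second_peaks(1.0, seed=42)
        assert len(blocked) >= 8 and len(control) >= 8
        assert abs(np.median(blocked) - 0.05) < 0.1
        res = mann_whitney_u(blocked, control)
        assert res.p_value < 0.01


class TestHeatmapMatrix:
    def _normalized(self, n_cells, seed=0):
        from calslice import default_config, generate_recording
        from calslice.preprocessing import compute_dff

        cfg = default_config(n_cells=n_cells, seed=seed)
        rec, truth = generate_recording(cfg)
        return compute_dff(rec), truth

    def test_group_boundary_positions(self):
        norm, _ = self._normalized(5)
        profiles = [ResponseProfile(c, True, frozenset({"denatonium"}))
                    for c in norm.cell_ids[:3]]
        profiles += [ResponseProfile(c, True, frozenset({"saccharin"}))
                     for c in norm.cell_ids[3:]]
        matrix, rows, boundaries = heatmap_matrix(norm, profiles)
        assert matrix.shape[0] == 5
        assert boundaries == [3]

    def test_empty_profiles_give_empty_matrix(self):
        norm, _ = self._normalized(3)
        matrix, rows, boundaries = heatmap_matrix(norm, [])
        assert matrix.shape[0] == 0 and rows == [] and boundaries == []

    def test_row_order_stable_under_input_permutation(self, rng):
        norm, _ = self._normalized(8, seed=5)
        profiles = [
            ResponseProfile(c, True,
                            frozenset({"denatonium"} if i % 2 else {"saccharin"}))
            for i, c in enumerate(norm.cell_ids)
        ]
        _, rows1, b1 = heatmap_matrix(norm, profiles)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        _, rows2, b2 = heatmap_matrix(norm, shuffled)
        assert rows1 == rows2 and b1 == b2
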