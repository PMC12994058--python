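"""Unit and property tests for the percentile-threshold scoring rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from fspheno.scoring import (
    COMPOSITE_VARIABLES,
    Direction,
    Rule,
    StartleSession,
    VariableSpec,
    assign_score,
    build_thresholds,
    composite_score,
    compute_percentile,
    radar_domain_scores,
    score_cohort,
    startle_habituation_ratios,
    variable_dispersion_ranking,
)

FS_TAIL_SPEC = VariableSpec("freezing_pct", "new_context", 16, Rule.FS_TAIL,
                            Direction.HIGHER_IS_WORSE)
EPM_SPEC = VariableSpec("open_arm_time_pct", "epm", 18, Rule.BIDIRECTIONAL,
                        Direction.LOWER_IS_WORSE)
AMP_SPEC = VariableSpec("amplitude_ratio", "startle", 23, Rule.STARTLE_RATIO,
                        Direction.HIGHER_IS_WORSE)
LAT_SPEC = VariableSpec("latency_to_peak_ratio", "startle", 23, Rule.STARTLE_RATIO,
                        Direction.LOWER_IS_WORSE)


class TestComputePercentile:
    def test_median_of_odd_length_list(self):
        assert compute_percentile([1, 2, 3, 4, 5], 50) == 3

    def test_boundary_percentiles_are_min_and_max(self):
        values = [7.5, -2.0, 3.0, 11.0]
        assert compute_percentile(values, 0) == -2.0
        assert compute_percentile(values, 100) == 11.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            compute_percentile([], 50)

    def test_matches_sort_interpolate_oracle(self, rng):
        for _ in range(300):
            values = rng.normal(size=12)
            for p in (5, 25, 75, 95):
                assert compute_percentile(values, p) == pytest.approx(
                    oracle.percentile_oracle(values, p), abs=1e-12
                )


class TestBuildThresholds:
    def test_fs_tail_with_null_controls_uses_fs_percentiles(self, rng):
        """Control values too low to grade: cut0 is the control max, the
        upper cuts come from the FS dataset."""
        fs = rng.uniform(0, 80, size=31)
        ts = build_thresholds(FS_TAIL_SPEC, [0.0] * 16, fs)
        assert ts.cuts["nofs_p95"] == 0.0
        assert ts.cuts["fs_p75"] == pytest.approx(oracle.percentile_oracle(fs, 75))
        assert ts.cuts["fs_p95"] == pytest.approx(oracle.percentile_oracle(fs, 95))

    def test_bidirectional_bins_symmetric_about_median(self):
        ctrl = np.concatenate([-np.arange(1, 11.0), np.arange(1, 11.0)])
        ts = build_thresholds(EPM_SPEC, ctrl)
        assert ts.cuts["p25"] == pytest.approx(-ts.cuts["p75"])
        assert ts.cuts["p5"] == pytest.approx(-ts.cuts["p95"])

    def test_every_cut_matches_its_declared_provenance(self, rng):
        """Provenance replay: each cut equals the oracle percentile of the
        dataset its provenance string names."""
        for _ in range(50):
            ctrl = rng.normal(10, 3, size=16)
            fs = rng.normal(20, 8, size=31)
            ts = build_thresholds(FS_TAIL_SPEC, ctrl, fs)
            assert ts.cuts["nofs_p95"] == pytest.approx(oracle.percentile_oracle(ctrl, 95))
            tb = build_thresholds(EPM_SPEC, ctrl)
            for name, p in (("p5", 5), ("p25", 25), ("p75", 75), ("p95", 95)):
                assert tb.cuts[name] == pytest.approx(oracle.percentile_oracle(ctrl, p))
            assert tb.cuts["min"] == ctrl.min() and tb.cuts["max"] == ctrl.max()

    def test_undersampled_controls_rejected(self):
        with pytest.raises(ValueError, match="undersampled"):
            build_thresholds(EPM_SPEC, [1.0, 2.0, 3.0])


class TestAssignScore:
    def test_startle_gates_are_inclusive_on_hyperarousal_side(self, rng):
        ctrl = rng.normal(0.8, 0.1, 16)
        amp = build_thresholds(AMP_SPEC, ctrl)
        assert assign_score(0.95, amp) >= 1
        assert assign_score(0.9499, amp) == 0
        lat = build_thresholds(LAT_SPEC, rng.normal(1.0, 0.1, 16))
        assert assign_score(1.05, lat) >= 1
        assert assign_score(1.0501, lat) == 0

    def test_value_on_fs_tail_cut_takes_lower_severity(self, rng):
        ts = build_thresholds(FS_TAIL_SPEC, rng.uniform(0, 5, 16), rng.uniform(0, 80, 31))
        for name, score in (("nofs_p95", 0), ("fs_p75", 1), ("fs_p95", 2)):
            assert assign_score(ts.cuts[name], ts) == score

    def test_non_finite_value_is_missing(self, rng):
        ts = build_thresholds(FS_TAIL_SPEC, rng.uniform(0, 5, 16), rng.uniform(0, 80, 31))
        assert assign_score(float("nan"), ts) is None

    def test_matches_bin_scan_oracle_on_random_cases(self, rng):
        """All three rules against an independent interval-scan oracle."""
        for _ in range(200):
            ctrl = rng.normal(rng.uniform(-5, 30), rng.uniform(0.5, 10), 16)
            fs = rng.normal(rng.uniform(0, 60), rng.uniform(0.5, 15), 31)
            fs_ts = build_thresholds(FS_TAIL_SPEC, ctrl, fs)
            bi_ts = build_thresholds(EPM_SPEC, ctrl)
            amp_ts = build_thresholds(AMP_SPEC, np.abs(ctrl) / 20 + 0.5)
            lat_ts = build_thresholds(LAT_SPEC, np.abs(ctrl) / 20 + 0.8)
            for v in rng.uniform(-20, 90, size=20):
                assert assign_score(v, fs_ts) == oracle.fs_tail_score_oracle(
                    v, fs_ts.cuts["nofs_p95"], fs_ts.cuts["fs_p75"], fs_ts.cuts["fs_p95"])
                assert assign_score(v, bi_ts) == oracle.bidirectional_score_oracle(
                    v, bi_ts.cuts, lower_is_worse=True)
                r = abs(v) / 30 + 0.2
                assert assign_score(r, amp_ts) == oracle.startle_score_oracle(
                    r, amp_ts.cuts["gate"], amp_ts.cuts["c1"], amp_ts.cuts["c2"], True)
                assert assign_score(r, lat_ts) == oracle.startle_score_oracle(
                    r, lat_ts.cuts["gate"], lat_ts.cuts["c1"], lat_ts.cuts["c2"], False)

    def test_monotone_in_severity_direction(self, rng):
        """Scores never decrease as the value moves further in the adverse
        direction, for every rule."""
        ctrl = rng.normal(20, 5, 16)
        fs = rng.normal(40, 15, 31)
        grids = [
            (build_thresholds(FS_TAIL_SPEC, ctrl, fs), np.linspace(-10, 100, 400)),
            (build_thresholds(AMP_SPEC, np.abs(ctrl) / 25), np.linspace(0, 3, 400)),
        ]
        for ts, grid in grids:
            scores = [assign_score(v, ts) for v in grid]
            assert all(b >= a for a, b in zip(scores, scores[1:]))
        # bidirectional, adverse = downward: non-increasing value => non-decreasing score
        bi = build_thresholds(EPM_SPEC, ctrl)
        down = np.linspace(ctrl.mean(), -20, 400)
        scores = [assign_score(v, bi) for v in down]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestStartleHabituation:
    def _session(self, amp, lat, flags=None):
        n = len(amp)
        return StartleSession(amp, lat, flags if flags is not None else np.zeros(n, bool))

    def test_direct_arithmetic(self):
        amp = [10.0] * 5 + [7.0] * 30 + [5.0] * 5
        lat = [100.0] * 40
        ratios = startle_habituation_ratios(self._session(amp, lat))
        assert ratios == (0.5, 1.0)

    def test_identical_trials_give_unit_ratios(self):
        s = self._session([3.0] * 40, [80.0] * 40)
        assert startle_habituation_ratios(s) == (1.0, 1.0)

    def test_flagged_trials_are_excluded(self, rng):
        amp = rng.uniform(1, 10, 40)
        lat = rng.uniform(50, 150, 40)
        flags = np.zeros(40, bool)
        flags[[1, 37]] = True
        got = startle_habituation_ratios(self._session(amp, lat, flags))
        keep = np.flatnonzero(~flags)
        first, last = keep[:5], keep[-5:]
        assert got[0] == pytest.approx(np.median(amp[last]) / np.median(amp[first]))
        assert got[1] == pytest.approx(np.median(lat[last]) / np.median(lat[first]))

    def test_zero_first_window_median_is_missing(self):
        with pytest.warns(UserWarning):
            a, _ = startle_habituation_ratios(
                self._session([0.0] * 5 + [1.0] * 35, [100.0] * 40))
        assert math.isnan(a)

    def test_too_few_valid_trials_is_missing(self):
        flags = np.ones(40, bool)
        flags[:4] = False
        a, l = startle_habituation_ratios(
            self._session(np.ones(40), np.ones(40), flags))
        assert math.isnan(a) and math.isnan(l)


class TestCompositeAndRadar:
    def _scores(self, values):
        return {spec.key: v for spec, v in zip(COMPOSITE_VARIABLES, values)}

    def test_floor_and_ceiling(self):
        assert composite_score(self._scores([0] * 8)) == 0
        assert composite_score(self._scores([3] * 8)) == 24

    def test_arithmetic(self):
        assert composite_score(self._scores([3, 2, 0, 1, 0, 0, 2, 1])) == 9

    def test_missing_component_voids_composite(self):
        scores = self._scores([1] * 8)
        scores[COMPOSITE_VARIABLES[0].key] = None
        assert math.isnan(composite_score(scores))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 3), min_size=8, max_size=8))
    def test_composite_equals_component_sum_and_bounds(self, vals):
        total = composite_score(self._scores(vals))
        assert total == sum(vals)
        assert 0 <= total <= 24

    def test_radar_domains_sum_components(self):
        scores = self._scores([2, 1, 0, 0, 3, 3, 0, 0])
        scores[("cue_reminder", 14, "freezing_pct")] = 3
        scores[("cue_reminder", 14, "escaping_pct")] = 3
        domains = radar_domain_scores(scores)
        assert domains["intrusion"] == 6
        assert domains["avoidance"] == 6
        assert domains["altered_reactivity"] == 3
        assert domains["altered_arousal"] == 0
        assert all(0 <= v <= 6 for v in domains.values())


class TestDispersionRanking:
    def test_two_variable_sort(self):
        rows = []
        for i, (v, sd) in enumerate([("a", 5.0), ("b", 1.0)]):
            for j, x in enumerate([-sd, 0.0, sd]):
                rows.append((f"m{j}", "Frz", "t", 1, v, x))
        table = pd.DataFrame(rows, columns=["animal_id", "group", "test", "day",
                                            "variable", "value"])
        ranked = variable_dispersion_ranking(table)
        assert list(ranked["variable"]) == ["a", "b"]

    def test_constant_table_ranks_all_zero_sd(self):
        rows = [(f"m{j}", "Frz", "t", 1, v, 1.0) for v in "ab" for j in range(3)]
        table = pd.DataFrame(rows, columns=["animal_id", "group", "test", "day",
                                            "variable", "value"])
        ranked = variable_dispersion_ranking(table)
        assert (ranked["sd"] == 0).all()

    def test_matches_recompute_and_sort_oracle(self, large_cohort):
        ranked = variable_dispersion_ranking(large_cohort)
        fs = large_cohort[large_cohort["group"] != "NoFS"]
        expect = (fs.groupby(["test", "day", "variable"])["value"].std()
                  .sort_values(ascending=False))
        got = list(zip(ranked["test"], ranked["day"], ranked["variable"]))
        assert got == list(expect.index)


class TestScoreCohort:
    def test_controls_score_zero_on_fs_tail_when_below_cut(self, scored_large_cohort):
        """Control animals at or below their own 95th-percentile cut score 0
        on FS-tail variables; at most ~5% can exceed it by construction."""
        _, scorecard, _ = scored_large_cohort
        ctrl = scorecard[scorecard["group"] == "NoFS"]
        frac_zero = (ctrl["score:new_context/freezing_pct"] == 0).mean()
        assert frac_zero >= 0.9

    def test_composite_matches_sum_of_reported_columns(self, scored_large_cohort):
        _, scorecard, _ = scored_large_cohort
        cols = [f"score:{s.test}/{s.name}" for s in COMPOSITE_VARIABLES]
        ok = scorecard[cols].notna().all(axis=1)
        assert np.allclose(scorecard.loc[ok, cols].sum(axis=1),
                           scorecard.loc[ok, "composite"])
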