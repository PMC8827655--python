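"""Event statistics: filtering, state grouping, transitions, fits, testing protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import astromap as am
from astromap.behavior import Transition
from astromap.events import (
    EventTable,
    compare_size_tails,
    summaries_to_frame,
    transition_profile,
)
from conftest import make_labels, rest_labels

META = {"pixel_size_um": 0.1836, "frame_rate_hz": 10.3, "grid_shape": [64, 64], "n_frames": 10000}


def table_from(rows, meta=None):
    df = pd.DataFrame(rows)
    for col, default in (("id", range(len(df))), ("dff_max", 1.0), ("area_um2", 5.0)):
        if col not in df.columns:
            df[col] = default
    return EventTable(df, dict(meta or META))


class TestLoadAndFilter:
    def test_size_floor_keeps_boundary(self):
        t = table_from(
            {"t0_frame": [0, 0, 0], "t1_frame": [5, 5, 5], "area_um2": [1.5, 2.0, 6.6]}
        )
        out = am.load_and_filter_events(t)
        assert sorted(out.df.area_um2) == [2.0, 6.6]

    def test_empty_table_passes(self):
        t = table_from({"t0_frame": [], "t1_frame": [], "area_um2": []})
        assert len(am.load_and_filter_events(t)) == 0

    def test_reversed_interval_rejected_with_row(self):
        t = table_from({"t0_frame": [0, 9], "t1_frame": [5, 3], "area_um2": [5.0, 5.0]})
        with pytest.raises(ValueError, match=r"row\(s\) \[1\]"):
            am.load_and_filter_events(t)

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="t0_frame"):
            EventTable(pd.DataFrame({"id": [1]}), META)

    def test_duration_derived_from_frames(self):
        t = table_from({"t0_frame": [0], "t1_frame": [103]})
        assert t.df.duration_s[0] == pytest.approx(10.0)


class TestAssignStates:
    def test_onset_in_stim_window_tagged_stimulation(self):
        base = ["run"] * 100
        labels = make_labels(base)
        labels.sub_state[40:56] = "vibrissa_stimulation"
        t = table_from({"t0_frame": [45], "t1_frame": [60]})
        out = am.assign_states(t, labels)
        assert out.df.state[0] == "vibrissa_stimulation"

    def test_all_rest_labels(self):
        labels = rest_labels(50)
        t = table_from({"t0_frame": [0, 10, 100], "t1_frame": [5, 15, 110]})
        assert set(am.assign_states(t, labels).df.state) == {"rest"}

    def test_vectorized_matches_per_event_lookup(self):
        rng = np.random.default_rng(8)
        base = rng.choice(["rest", "run"], size=500)
        labels = make_labels(base)
        t0 = rng.integers(0, 500, size=200)
        t = table_from({"t0_frame": t0, "t1_frame": t0 + 3})
        out = am.assign_states(t, labels)
        eff = labels.effective_state()
        assert all(out.df.state.iloc[i] == eff[t0[i]] for i in range(200))

    def test_onset_beyond_labels_rejected(self):
        labels = rest_labels(1.0)
        t = table_from({"t0_frame": [999], "t1_frame": [1000]})
        with pytest.raises(ValueError):
            am.assign_states(t, labels)


class TestStateSummary:
    def test_frequency_is_count_over_state_seconds(self):
        labels = rest_labels(100.0)
        n = 95
        t = table_from({"t0_frame": np.arange(n), "t1_frame": np.arange(n) + 2})
        summ = {s.state: s for s in am.state_summary(t, labels)}
        assert summ["rest"].frequency == pytest.approx(n / labels.seconds_in_state("rest"))
        assert summ["rest"].frequency == pytest.approx(0.95, rel=0.01)

    def test_unvisited_state_missing_and_partition(self):
        labels = rest_labels(10.0)
        t = table_from({"t0_frame": [1, 2], "t1_frame": [3, 4]})
        summ = {s.state: s for s in am.state_summary(t, labels)}
        assert np.isnan(summ["run"].frequency)  # never visited
        # base states partition all events; substates are overlapping subsets
        assert summ["rest"].n_events + summ["run"].n_events == len(t)

    def test_stimulation_events_still_count_as_run_activity(self):
        base = ["run"] * 100
        labels = make_labels(base)
        labels.sub_state[40:56] = "vibrissa_stimulation"
        t = table_from({"t0_frame": [10, 45], "t1_frame": [12, 47]})
        summ = {s.state: s for s in am.state_summary(t, labels)}
        assert summ["run"].n_events == 2  # base granularity partitions events
        assert summ["vibrissa_stimulation"].n_events == 1

    def test_generator_rates_recovered_within_poisson_ci(self, small_cfg, small_scene):
        _, field = small_scene
        base = (["rest"] * int(500 * 10.3)) + (["run"] * int(500 * 10.3))
        labels = make_labels(base)
        table = am.sample_events(field, labels, small_cfg, footprints=False)
        table = am.assign_states(table, labels)
        summ = {s.state: s for s in am.state_summary(table, labels)}
        for state, rate in (("rest", 0.95), ("run", 3.7)):
            n_exp = rate * 500
            se = np.sqrt(n_exp) / 500
            assert abs(summ[state].frequency - rate) < 3 * se


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,comp,expected",
        [
            (19.6, 39.8, 103),  # cell bodies vs local background
            (2.4, 1.1, -54),  # locomotion offset frequency drop
            (0.95, 3.7, 289),  # locomotion onset frequency rise
            (8.1, 19.6, 142),  # 12-day background vs contralateral control
        ],
    )
    def test_printed_worked_examples(self, ref, comp, expected):
        assert round(am.percent_change(ref, comp)) == expected

    def test_identity_and_zero_reference(self):
        assert am.percent_change(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            am.percent_change(0.0, 1.0)

    def test_documented_asymmetry(self):
        p1 = am.percent_change(2.0, 3.0)
        p2 = am.percent_change(3.0, 2.0)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0)
        assert p1 != -p2


class TestTransitionProfile:
    def test_single_event_single_transition(self):
        t = table_from({"t0_frame": [int(10.5 * 10.3)], "t1_frame": [int(10.5 * 10.3) + 5]})
        trs = [Transition("rest_to_run", int(10 * 10.3), 10.0)]
        prof = transition_profile(t, trs, (-3, 6), 1.0)
        tab = prof.table
        hot = tab[(tab.bin_left == 0.0)]
        assert hot.frequency.iloc[0] == pytest.approx(1.0)
        assert tab[tab.bin_left != 0.0].frequency.max() == 0.0

    def test_reference_bin_is_minus_one_second(self):
        t = table_from({"t0_frame": [5], "t1_frame": [6]})
        prof = transition_profile(t, [Transition("rest_to_run", 103, 10.0)], (-3, 6), 1.0)
        ref = prof.table[prof.table.is_reference]
        assert ref.bin_left.iloc[0] == -1.0

    def test_flat_profile_on_homogeneous_poisson(self):
        rng = np.random.default_rng(21)
        fr = 10.3
        n_frames = 30000
        onsets = np.flatnonzero(rng.random(n_frames) < 2.0 / fr)
        t = table_from({"t0_frame": onsets, "t1_frame": onsets + 3})
        trs = [Transition("rest_to_run", f, f / fr) for f in range(200, n_frames - 200, 300)]
        prof = transition_profile(t, trs, (-3, 6), 1.0)
        freqs = prof.table.frequency
        assert freqs.max() / freqs.min() < 1.4  # Poisson noise only, far from the 3.9 step
        assert not (prof.table.p_adj_frequency.dropna() < 0.05).any()


class TestUltrafast:
    def test_fraction_direct_count(self):
        fr = 10.0
        meta = dict(META, frame_rate_hz=fr)
        t = table_from(
            {"t0_frame": [0, 0, 0, 0], "t1_frame": [2, 3, 10, 20]}, meta
        )  # durations 0.2, 0.3, 1.0, 2.0
        res = am.ultrafast_stats(t)
        assert res.fraction == pytest.approx(0.5)

    def test_no_ultrafast(self):
        t = table_from({"t0_frame": [0, 0], "t1_frame": [50, 60]})
        assert am.ultrafast_stats(t).fraction == 0.0

    def test_fraction_matches_generator_cdf(self, small_cfg, small_scene):
        # closed-form: P(duration <= 0.3 s) under the configured margin,
        # with the frame-rounding the generator applies
        _, field = small_scene
        labels = rest_labels(2000.0, 10.3)
        cfg = am.GeneratorConfig(
            grid_shape=small_cfg.grid_shape, pixel_size=small_cfg.pixel_size, rate_rest=10.0, seed=9
        )
        table = am.sample_events(field, labels, cfg, footprints=False)
        res = am.ultrafast_stats(table, threshold=0.3)
        # duration_frames = max(2, round(d * fr)); <= 3 frames (0.29 s) iff d*fr < 3.5
        p_expected = stats.skewnorm.cdf(3.5 / 10.3, cfg.dur_shape, cfg.dur_loc, cfg.dur_scale)
        se = np.sqrt(p_expected * (1 - p_expected) / len(table))
        assert abs(res.fraction - p_expected) < 4 * se


class TestCorrelationAndFits:
    def test_perfectly_linear_pairs(self):
        t = table_from(
            {"t0_frame": np.zeros(10, int), "t1_frame": (np.arange(10) + 1) * 10,
             "area_um2": np.exp(np.arange(10) + 1.0)}
        )
        r, _ = am.size_duration_correlation(t)
        assert r == pytest.approx(1.0)

    def test_constant_input_undefined(self):
        t = table_from({"t0_frame": [0, 0, 0], "t1_frame": [5, 5, 5]})
        with pytest.warns(UserWarning):
            r, _ = am.size_duration_correlation(t)
        assert np.isnan(r)

    def test_skewnorm_symmetric_samples_shape_near_zero(self):
        rng = np.random.default_rng(2)
        fit = am.fit_skew_normal(rng.normal(5.0, 1.0, size=4000))
        assert abs(fit["shape"]) < 0.6
        assert fit["mean"] == pytest.approx(5.0, abs=0.1)

    def test_skewnorm_parameter_recovery(self):
        rng = np.random.default_rng(3)
        x = stats.skewnorm.rvs(3.0, loc=1.0, scale=0.5, size=8000, random_state=rng)
        fit = am.fit_skew_normal(x)
        assert fit["mean"] == pytest.approx(x.mean(), abs=0.02)
        assert 1.5 < fit["shape"] < 6.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            am.fit_skew_normal(np.ones(10))


class TestTailFits:
    def test_lognormal_beats_exponential(self):
        rng = np.random.default_rng(5)
        sizes = rng.lognormal(1.48, 0.9, size=4000)
        res = compare_size_tails(sizes, xmin=5.0)
        row = res.comparisons.query("family_1 == 'lognormal' and family_2 == 'exponential'")
        assert row.llr.iloc[0] > 0
        assert row.p_value.iloc[0] < 0.05
        assert res.best == "lognormal"

    def test_powerlaw_alpha_recovery(self):
        rng = np.random.default_rng(6)
        alpha = 2.5
        u = rng.random(5000)
        x = 5.0 * (1 - u) ** (-1.0 / (alpha - 1.0))
        res = compare_size_tails(x, xmin=5.0)
        assert res.params["power_law"]["alpha"] == pytest.approx(alpha, abs=0.1)

    def test_all_below_xmin_rejected(self):
        with pytest.raises(ValueError):
            compare_size_tails(np.full(500, 1.0), xmin=5.0)

    def test_ccdf_table_monotone(self):
        rng = np.random.default_rng(7)
        res = compare_size_tails(rng.lognormal(2.0, 0.8, size=2000), xmin=5.0)
        for col in ("empirical", "power_law", "lognormal", "exponential"):
            assert (np.diff(res.ccdf[col]) <= 1e-12).all()


class TestNormalizeToRest:
    def frame(self):
        return pd.DataFrame(
            {
                "recording_id": ["a", "a", "b", "b"],
                "state": ["rest", "run", "rest", "run"],
                "frequency": [0.95, 3.7, 1.2, 2.4],
                "mean_area_um2": [6.6, 10.8, 5.0, 7.5],
            }
        )

    def test_rest_rows_become_one_and_ratio(self):
        out = am.normalize_to_rest(self.frame())
        rest = out[out.state == "rest"]
        assert np.allclose(rest[["frequency", "mean_area_um2"]], 1.0)
        run_a = out.query("recording_id == 'a' and state == 'run'")
        assert run_a.frequency.iloc[0] == pytest.approx(3.7 / 0.95, rel=1e-6)
        assert run_a.frequency.iloc[0] == pytest.approx(3.89, abs=0.005)

    def test_scale_invariance(self):
        f = self.frame()
        g = f.copy()
        g[["frequency", "mean_area_um2"]] *= 13.7
        assert np.allclose(
            am.normalize_to_rest(f)[["frequency", "mean_area_um2"]],
            am.normalize_to_rest(g)[["frequency", "mean_area_um2"]],
        )

    def test_missing_rest_excluded_with_warning(self):
        f = self.frame().iloc[[1, 2, 3]]  # recording 'a' lost its rest row
        with pytest.warns(UserWarning, match="'a'"):
            out = am.normalize_to_rest(f)
        assert set(out.recording_id) == {"b"}


class TestCompareGroups:
    def test_identical_groups_null_center(self):
        res = am.compare_groups({"a": np.ones(10), "b": np.ones(10)})
        assert res["p_value"] == pytest.approx(1.0)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            res = am.compare_groups({"a": rng.normal(size=30), "b": rng.normal(size=30)})
            rejections += res["p_value"] < 0.05
        assert rejections / n_rep < 0.10  # ~5% expected

    def test_heavy_tails_select_nonparametric_branch(self):
        rng = np.random.default_rng(12)
        g = {"a": rng.standard_cauchy(200), "b": rng.standard_cauchy(200)}
        res = am.compare_groups(g)
        assert not res["all_normal"]
        assert "mann-whitney" in res["test"]
        assert all(d["method"] == "ks" for d in res["normality"].values())

    def test_small_samples_use_shapiro(self):
        rng = np.random.default_rng(13)
        res = am.compare_groups({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        assert all(d["method"] == "shapiro" for d in res["normality"].values())
        assert res["test"] == "unpaired t-test"

    def test_three_normal_groups_anova_tukey(self):
        rng = np.random.default_rng(14)
        g = {k: rng.normal(loc, 1.0, size=40) for k, loc in (("a", 0), ("b", 0), ("c", 2))}
        res = am.compare_groups(g)
        assert "ANOVA" in res["test"]
        assert res["p_value"] < 0.001
        assert res["posthoc"] is not None

    def test_three_skewed_groups_kruskal_bonferroni(self):
        rng = np.random.default_rng(15)
        g = {k: rng.lognormal(m, 1.0, size=120) for k, m in (("a", 0), ("b", 0), ("c", 1.5))}
        res = am.compare_groups(g)
        assert "kruskal" in res["test"]
        ph = res["posthoc"]
        assert (ph.p_bonferroni >= ph.p_raw - 1e-12).all()

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            am.compare_groups({"a": [1.0], "b": [1.0, 2.0]})


def test_summaries_roundtrip_to_frame(small_cfg, small_scene):
    _, field = small_scene
    labels = rest_labels(60.0)
    t = am.assign_states(am.sample_events(field, labels, small_cfg), labels)
    frame = summaries_to_frame(am.state_summary(t, labels), recording_id="r1")
    assert set(frame.state) == {"rest", "run", "vibrissa_stimulation", "vibrissa_exploration"}
    rest = frame[frame.state == "rest"].iloc[0]
    assert rest.n_events == len(t)
    assert rest.frequency * rest.seconds_in_state == pytest.approx(rest.n_events)
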