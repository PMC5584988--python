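"""Dive events, time fractions, sliding probabilities, intervals, ECDF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trajectory
from digdive import Mode, ModeTrack, ValidationError
from digdive.analyze import (
    cohort_aggregates,
    cohort_summary,
    correlate,
    ecdf,
    extract_dives,
    mode_time_fractions,
    post_dive_intervals,
    sliding_mode_probability,
    trial_summary,
)
from digdive.classify import classify_modes
from digdive.core import BehaviorThresholds
from digdive.simulate import preset_params, simulate_cohort


def track_of(codes, trial_id="t", dt=1.0):
    labels = np.array(list(codes))
    return ModeTrack(trial_id=trial_id, times=np.arange(len(labels)) * dt, labels=labels)


def traj_for(codes, depth=-6.0):
    z = np.array([depth if c == "V" else -1.0 for c in codes])
    return make_trajectory(z)


class TestExtractDives:
    def test_single_run_duration_and_depth(self):
        codes = "GVVVG"
        z = np.array([-1.0, -4.0, -6.0, -4.0, -1.0])
        events = extract_dives(track_of(codes), make_trajectory(z))
        assert len(events) == 1
        ev = events[0]
        assert ev.duration_s == 3.0
        assert ev.max_depth_mm == -6.0

    def test_no_diving_frames_empty_list(self):
        assert extract_dives(track_of("SGSGS"), traj_for("SGSGS")) == []

    @given(st.lists(st.sampled_from("SGVE"), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_events_equal_run_length_encoding_oracle(self, codes):
        codes = "".join(codes)
        events = extract_dives(track_of(codes), traj_for(codes))
        # brute-force RLE
        expected = []
        start = None
        for i, c in enumerate(codes + "$"):
            if c == "V" and start is None:
                start = i
            elif c != "V" and start is not None:
                expected.append((start, i - 1))
                start = None
        assert [(e.start_s, e.end_s - 1) for e in events] == [
            (float(s), float(t)) for s, t in expected
        ]

    def test_event_durations_sum_to_total_diving_time(self, mel_trial, geometry):
        traj, _ = mel_trial
        mt = classify_modes(traj, BehaviorThresholds(z_diving=-3.6), geometry)
        events = extract_dives(mt, traj)
        assert sum(e.duration_s for e in events) == mt.total_time_in(Mode.DIVING)

    def test_path_speed_exceeds_vertical_speed(self):
        codes = "VVVV"
        z = np.array([-4.0, -5.0, -6.0, -7.0])
        x = np.array([0.0, 0.3, 0.6, 0.9])
        traj = make_trajectory(z, x=x)
        path = extract_dives(track_of(codes), traj, speed="path")[0].mean_speed_mm_s
        vert = extract_dives(track_of(codes), traj, speed="vertical")[0].mean_speed_mm_s
        assert vert == pytest.approx(1.0)
        assert path == pytest.approx(np.hypot(1.0, 0.3))


class TestModeFractions:
    def test_even_split(self):
        f = mode_time_fractions(track_of("S" * 450 + "G" * 450))
        assert f[Mode.SURFACING] == 50.0 and f[Mode.DIGGING] == 50.0
        assert f[Mode.DIVING] == 0.0 and f[Mode.ESCAPING] == 0.0

    def test_all_diving(self):
        assert mode_time_fractions(track_of("V" * 10))[Mode.DIVING] == 100.0

    def test_all_excluded_rejected(self):
        with pytest.raises(ValidationError):
            mode_time_fractions(track_of("XXXX"))

    @given(st.lists(st.sampled_from("SGVEX"), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_fractions_match_counting_oracle_and_sum_to_100(self, codes):
        codes = "".join(codes)
        if all(c == "X" for c in codes):
            return
        f = mode_time_fractions(track_of(codes))
        n_active = sum(1 for c in codes if c != "X")
        for mode, code in [
            (Mode.SURFACING, "S"),
            (Mode.DIGGING, "G"),
            (Mode.DIVING, "V"),
            (Mode.ESCAPING, "E"),
        ]:
            assert f[mode] == pytest.approx(100.0 * codes.count(code) / n_active)
        assert sum(f.values()) == pytest.approx(100.0, abs=1e-9)


class TestSlidingProbability:
    def test_all_diving_probability_one(self):
        tracks = [track_of("V" * 50, f"t{i}") for i in range(3)]
        series = sliding_mode_probability(tracks, Mode.DIVING)
        np.testing.assert_allclose(series.probability, 1.0)

    def test_half_diving_probability_half(self):
        tracks = [track_of("V" * 40), track_of("S" * 40, "u")]
        series = sliding_mode_probability(tracks, Mode.DIVING)
        np.testing.assert_allclose(series.probability, 0.5)

    def test_window_of_one_sample_is_unsmoothed(self):
        rng = np.random.default_rng(0)
        tracks = [
            track_of("".join(rng.choice(list("SGV"), size=40)), f"t{i}") for i in range(4)
        ]
        series = sliding_mode_probability(tracks, Mode.DIVING, window_s=1.0)
        raw = np.mean(np.stack([t.labels == "V" for t in tracks]), axis=0)
        np.testing.assert_allclose(series.probability, raw)

    def test_matches_brute_force_windowed_mean(self):
        rng = np.random.default_rng(1)
        tracks = [
            track_of("".join(rng.choice(list("SGVX"), size=80)), f"t{i}") for i in range(5)
        ]
        series = sliding_mode_probability(tracks, Mode.DIVING, window_s=10.0)
        labels = np.stack([t.labels for t in tracks])
        active = labels != "X"
        with np.errstate(invalid="ignore"):
            p_raw = np.where(active.sum(0) > 0, (labels == "V").sum(0) / active.sum(0), np.nan)
        half = 5
        for t in range(80):
            lo, hi = max(0, t - half), min(80, t + half + 1)
            seg = p_raw[lo:hi]
            seg = seg[np.isfinite(seg)]
            expect = seg.mean() if seg.size else np.nan
            if np.isnan(expect):
                assert np.isnan(series.probability[t])
            else:
                assert series.probability[t] == pytest.approx(expect)

    def test_probability_bounds(self):
        rng = np.random.default_rng(2)
        tracks = [
            track_of("".join(rng.choice(list("SGVE"), size=100)), f"t{i}") for i in range(6)
        ]
        series = sliding_mode_probability(tracks, Mode.DIVING)
        p = series.probability
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            sliding_mode_probability([], Mode.DIVING)


class TestPostDiveIntervals:
    def test_single_pair(self):
        pairs = post_dive_intervals(track_of("V" * 10 + "G" * 5 + "V" * 3))
        assert pairs == [(10.0, 5.0)]

    def test_trailing_dive_censored(self):
        assert post_dive_intervals(track_of("G" * 5 + "V" * 10)) == []

    @given(st.lists(st.sampled_from("SGV"), min_size=3, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_pairs_match_segmentation_oracle(self, codes):
        codes = "".join(codes)
        pairs = post_dive_intervals(track_of(codes))
        # brute-force segmentation
        runs = []
        i = 0
        while i < len(codes):
            j = i
            while j < len(codes) and codes[j] == codes[i]:
                j += 1
            runs.append((codes[i], i, j - 1))
            i = j
        dives = [r for r in runs if r[0] == "V"]
        expected = []
        for a, b in zip(dives[:-1], dives[1:]):
            between = codes[a[2] + 1 : b[1]]
            expected.append(
                (float(a[2] - a[1] + 1), float(sum(1 for c in between if c in "SG")))
            )
        assert pairs == expected


class TestCorrelate:
    def test_monotone_rho_one(self):
        assert correlate([(1, 2), (2, 4), (3, 9)])[0] == pytest.approx(1.0)

    def test_constant_margin_nan(self):
        rho, p = correlate([(1, 5), (2, 5), (3, 5)])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate([(1, 2), (3, 4)])

    def test_exact_permutation_p_matches_enumeration_oracle(self):
        from itertools import permutations
        from scipy.stats import rankdata

        rng = np.random.default_rng(3)
        for n in (5, 6, 7):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            rho, p = correlate(list(zip(a, b)))
            # independent enumeration via rank products
            ra, rb = rankdata(a), rankdata(b)
            obs = np.corrcoef(ra, rb)[0, 1]
            hits = 0
            total = 0
            for perm in permutations(rb):
                r = np.corrcoef(ra, np.array(perm))[0, 1]
                hits += abs(r) >= abs(obs) - 1e-12
                total += 1
            assert rho == pytest.approx(obs)
            assert p == pytest.approx(hits / total)


class TestECDF:
    def test_single_value(self):
        support, frac = ecdf([2.0])
        assert support.tolist() == [2.0] and frac.tolist() == [1.0]

    def test_duplicates(self):
        support, frac = ecdf([1, 2, 2, 4])
        i = np.searchsorted(support, 2.0)
        assert frac[i] == pytest.approx(0.75)

    def test_terminal_value_is_one_and_nondecreasing(self):
        rng = np.random.default_rng(0)
        _, frac = ecdf(rng.normal(size=100))
        assert frac[-1] == pytest.approx(1.0)
        assert np.all(np.diff(frac) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ecdf([])


class TestCohortSummary:
    def test_single_surfacing_trial(self):
        mt = track_of("S" * 20)
        df = cohort_summary([mt], [traj_for("S" * 20)])
        assert len(df) == 1
        assert df.loc[0, "n_dives"] == 0
        assert df.loc[0, "pct_surfacing"] == 100.0

    def test_aggregates_equal_recomputation(self, geometry):
        params = preset_params("mel_0.4_noodor")
        pairs = simulate_cohort(params, 12, seed=3, geometry=geometry)
        thr = BehaviorThresholds(z_diving=params.dive_threshold_mm)
        mts = [classify_modes(t, thr, geometry) for t, _ in pairs]
        df = cohort_summary(mts, [t for t, _ in pairs])
        agg = cohort_aggregates(df)
        assert agg["dives_per_trial_mean"] == pytest.approx(df["n_dives"].mean())
        assert agg["pct_diving_mean"] == pytest.approx(df["pct_diving"].mean())
        assert agg["n_trials"] == len(df)

    def test_simulated_cohort_dive_count_near_anchor(self, geometry):
        """Preset calibration: mean dives/trial within 20% of 4.1."""
        params = preset_params("mel_0.4_noodor")
        pairs = simulate_cohort(params, 200, seed=1, geometry=geometry)
        thr = BehaviorThresholds(z_diving=params.dive_threshold_mm)
        mts = [classify_modes(t, thr, geometry) for t, _ in pairs]
        df = cohort_summary(mts, [t for t, _ in pairs])
        assert df["n_dives"].mean() == pytest.approx(4.1, rel=0.2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cohort_summary([], [])

    def test_trial_summary_counts_match_events(self, mel_trial, geometry):
        traj, _ = mel_trial
        mt = classify_modes(traj, BehaviorThresholds(z_diving=-3.6), geometry)
        s = trial_summary(mt, traj)
        assert s.n_dives == len(extract_dives(mt, traj))
        assert s.pct_surfacing + s.pct_digging + s.pct_diving + s.pct_escaping == pytest.approx(100.0)
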