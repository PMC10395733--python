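import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from eogadhd import (
    RsotResult,
    SaccadeEvent,
    StimulusEvent,
    StimulusSchedule,
    SubjectProfile,
    assemble_features,
    cgd_rate,
    detect_events,
    extract_features,
    higuchi_fd,
    hjorth_params,
    rsot_match,
    simulate_subject,
    success_rates,
    weighted_success,
)
from eogadhd.features import HjorthTriple, round2
from eogadhd.preprocess import downsample, normalize_amplitude

pct = st.floats(0.0, 100.0, allow_nan=False)


# ---------------------------------------------------------------------------
# saccade detection


class TestDetectEvents:
    def test_flat_signal_yields_no_events(self):
        assert detect_events(np.zeros(200), "H") == []

    def test_single_step_yields_one_signed_event(self):
        x = np.zeros(100)
        x[50:] = 1.0
        events = detect_events(x, "H")
        assert len(events) == 1
        assert events[0].direction == "right"
        down = detect_events(1.0 - x, "V")
        assert len(down) == 1 and down[0].direction == "down"

    def test_perfect_tracker_events_match_truth_log(self, small_schedule):
        profile = SubjectProfile(
            p_track=1.0, latency_mean=0.0, latency_sd=0.0, drift_sd=0.0,
            noise_sd=0.0, blink_rate=0.0, spontaneous_rate=0.0,
        )
        rec = simulate_subject(small_schedule, profile, seed=0)
        clean = normalize_amplitude(downsample(rec))
        for ch in ("H", "V"):
            events = detect_events(clean.channel(ch), ch, rate=clean.rate)
            truth = [t for t in rec.truth if t.channel == ch]
            assert len(events) == len(truth)
            for e, t in zip(events, truth):
                assert e.direction == t.direction
                assert abs(e.time - t.time) <= 0.1


# ---------------------------------------------------------------------------
# one-to-one matching


def _stimulus(onset, direction, stage=1, x=0.5, y=0.5):
    return StimulusEvent(onset=onset, x=x, y=y, direction=direction,
                         stage=stage, colour="red")


def _event(time, direction, pos=0.5):
    ch = "H" if direction in ("left", "right") else "V"
    return SaccadeEvent(time=time, direction=direction, magnitude=0.3,
                        position_estimate=pos, channel=ch)


def _schedule(stimuli, durations=(10.0,)):
    return StimulusSchedule(events=tuple(stimuli), stage_durations=durations)


class TestRsotMatch:
    def test_all_compatible_pairs_match(self):
        sched = _schedule([_stimulus(t, "right") for t in (1.0, 3.0, 5.0)])
        events = [_event(t + 0.2, "right") for t in (1.0, 3.0, 5.0)]
        result = rsot_match(events, sched, pos_tol=None)
        assert result.matches.loc[1, "right"] == 3

    def test_one_to_one_constraint(self):
        sched = _schedule([_stimulus(1.0, "right"), _stimulus(1.4, "right")])
        result = rsot_match([_event(1.2, "right")], sched, pos_tol=None)
        assert result.matches.loc[1, "right"] == 1

    def test_direction_must_agree(self):
        sched = _schedule([_stimulus(1.0, "right")])
        result = rsot_match([_event(1.0, "left")], sched, pos_tol=None)
        assert result.matches.to_numpy().sum() == 0

    def test_position_tolerance_filters_matches(self):
        sched = _schedule([_stimulus(1.0, "right", x=0.9)])
        assert rsot_match([_event(1.1, "right", pos=0.2)], sched,
                          pos_tol=0.15).matches.to_numpy().sum() == 0
        assert rsot_match([_event(1.1, "right", pos=0.85)], sched,
                          pos_tol=0.15).matches.to_numpy().sum() == 1

    def test_negative_tolerance_rejected(self):
        sched = _schedule([_stimulus(1.0, "right")])
        with pytest.raises(ValueError):
            rsot_match([], sched, time_tol=-1.0)

    def test_matches_equal_bruteforce_oracle_on_random_instances(self, matching_oracle):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_s = rng.integers(1, 11)
            n_e = rng.integers(0, 11)
            t_tol = rng.uniform(0.1, 1.0)
            p_tol = rng.uniform(0.05, 0.5) if rng.random() < 0.5 else None
            s_t = np.sort(rng.uniform(0, 10, n_s))
            s_p = rng.uniform(0, 1, n_s)
            e_t = rng.uniform(0, 10, n_e)
            e_p = rng.uniform(0, 1, n_e)
            sched = _schedule(
                [_stimulus(t, "right", x=p) for t, p in zip(s_t, s_p)]
            )
            events = [_event(t, "right", pos=p) for t, p in zip(e_t, e_p)]
            got = rsot_match(events, sched, time_tol=t_tol, pos_tol=p_tol)
            compat = np.abs(e_t[None, :] - s_t[:, None]) <= t_tol
            if p_tol is not None:
                compat &= np.abs(e_p[None, :] - s_p[:, None]) <= p_tol
            assert got.matches.to_numpy().sum() == matching_oracle(compat)


class TestSuccessRates:
    def _result(self, matches):
        refs = pd.DataFrame(
            {"left": [40] * 3, "right": [40] * 3, "up": [30] * 3, "down": [30] * 3},
            index=[1, 2, 3],
        )
        return RsotResult(matches=matches, references=refs)

    def test_published_example_cells(self):
        # group-mean matched counts over their references
        assert round2(100 * 13.05 / 40) == 32.63
        matches = self._result(
            pd.DataFrame(
                {"left": [13.05, 11.87, 13.15], "right": [10.97, 9.87, 10.03],
                 "up": [7.23, 8.67, 8.64], "down": [6.72, 8.03, 9.15]},
                index=[1, 2, 3],
            )
        )
        filled = success_rates(matches)
        assert round2(filled.success.loc[1, "left"]) == 32.63
        assert round2(filled.success.loc[1, "up"]) == 24.10
        assert round2(filled.direction_accuracy["left"]) == 31.73

    def test_zero_matches_give_zero_rates(self):
        refs_like = pd.DataFrame(
            {"left": [0] * 3, "right": [0] * 3, "up": [0] * 3, "down": [0] * 3},
            index=[1, 2, 3], dtype=float,
        )
        filled = success_rates(self._result(refs_like))
        assert (filled.success == 0).all().all()
        assert filled.weighted == 0.0

    def test_zero_reference_rejected(self):
        refs = pd.DataFrame({"left": [0], "right": [1], "up": [1], "down": [1]}, index=[1])
        result = RsotResult(matches=refs * 0, references=refs)
        with pytest.raises(ValueError):
            success_rates(result)


class TestWeightedSuccess:
    @pytest.mark.parametrize(
        "accs,expected",
        [
            ((31.73, 25.73, 27.26, 26.55), 28.07),   # drug-free ADHD
            ((33.03, 27.10, 27.61, 26.72), 29.02),   # treated ADHD
            ((36.43, 29.98, 31.32, 30.70), 32.41),   # healthy controls
        ],
    )
    def test_published_group_scores(self, accs, expected):
        assert round2(weighted_success(*accs)) == expected

    @given(pct)
    def test_equal_inputs_are_a_fixed_point(self, p):
        assert weighted_success(p, p, p, p) == pytest.approx(p)

    @given(pct, pct, pct, pct, pct)
    def test_monotone_and_bounded(self, l, r, u, d, bump):
        base = weighted_success(l, r, u, d)
        assert min(l, r, u, d) - 1e-9 <= base <= max(l, r, u, d) + 1e-9
        l2 = min(100.0, l + bump)
        assert weighted_success(l2, r, u, d) >= base - 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            weighted_success(101.0, 50.0, 50.0, 50.0)


# ---------------------------------------------------------------------------
# complexity / statistical descriptors


class TestHiguchiFd:
    def test_linear_ramp_has_dimension_one(self):
        fd = higuchi_fd(np.linspace(0.0, 1.0, 1000), kmax=8)
        assert fd == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_approaches_two(self):
        fds = [
            higuchi_fd(np.random.default_rng(s).normal(size=2000), kmax=8)
            for s in range(20)
        ]
        assert abs(np.mean(fds) - 2.0) < 0.1

    @given(st.floats(0.1, 100.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(3).normal(size=500).cumsum()
        assert higuchi_fd(a * x + b) == pytest.approx(higuchi_fd(x), rel=1e-9)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.zeros(10), kmax=8)


class TestHjorth:
    def test_sinusoid_closed_forms(self):
        fs, f = 20.0, 1.0
        t = np.arange(0, 10, 1 / fs)       # integer number of periods
        triple = hjorth_params(np.sin(2 * np.pi * f * t))
        assert triple.activity == pytest.approx(0.5, rel=0.01)
        assert triple.mobility == pytest.approx(2 * np.sin(np.pi * f / fs), rel=0.01)

    @given(st.floats(0.01, 50.0))
    def test_scale_homogeneity(self, a):
        x = np.random.default_rng(5).normal(size=400)
        base = hjorth_params(x)
        scaled = hjorth_params(a * x)
        assert scaled.activity == pytest.approx(a**2 * base.activity, rel=1e-9)
        assert scaled.mobility == pytest.approx(base.mobility, rel=1e-9)
        assert scaled.complexity == pytest.approx(base.complexity, rel=1e-9)

    def test_white_noise_activity_matches_variance(self):
        x = np.random.default_rng(6).normal(0.0, 1.0, 5000)
        assert hjorth_params(x).activity == pytest.approx(1.0, rel=0.05)

    def test_complexity_at_least_one(self):
        x = np.random.default_rng(7).normal(size=1000)
        assert hjorth_params(x).complexity >= 1.0 - 1e-9

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            hjorth_params(np.full(100, 2.0))


class TestCgdRate:
    def test_basic_percentage(self):
        assert cgd_rate([True] * 39 + [False] * 61) == 39.00
        assert cgd_rate([False, False]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cgd_rate([])


# ---------------------------------------------------------------------------
# feature assembly and end-to-end extraction


class TestFeatureVector:
    def _pieces(self):
        refs = pd.DataFrame(
            {"left": [4] * 3, "right": [4] * 3, "up": [3] * 3, "down": [3] * 3},
            index=[1, 2, 3],
        )
        rsot = success_rates(RsotResult(matches=refs.copy(), references=refs))
        cells = {(s, c) for s in (1, 2, 3) for c in ("H", "V")}
        hfd = {k: 1.1 for k in cells}
        hjorth = {k: HjorthTriple(0.1, 0.02, 1.5) for k in cells}
        return rsot, hfd, hjorth

    def test_vector_has_26_entries(self):
        rsot, hfd, hjorth = self._pieces()
        fv = assemble_features(rsot, 1, hfd, hjorth)
        assert len(fv.to_series()) == 26

    def test_missing_stage_rejected(self):
        rsot, hfd, hjorth = self._pieces()
        del hfd[(2, "H")]
        with pytest.raises(ValueError):
            assemble_features(rsot, 0, hfd, hjorth)

    def test_extraction_deterministic(self, small_schedule):
        rec = simulate_subject(small_schedule, SubjectProfile(), seed=4)
        a = extract_features(rec, small_schedule, cgd=1).to_series()
        b = extract_features(rec, small_schedule, cgd=1).to_series()
        pd.testing.assert_series_equal(a, b)

    def test_perfect_tracker_scores_near_hundred(self, small_schedule):
        rec = simulate_subject(small_schedule, SubjectProfile.perfect(), seed=2)
        fv = extract_features(rec, small_schedule, cgd=1)
        assert fv.rsot_weighted >= 95.0
        assert fv.channel_means().shape == (3, 4)
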