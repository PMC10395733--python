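import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from eogadhd import (
    EogRecording,
    SsaConfig,
    SubjectProfile,
    downsample,
    normalize_amplitude,
    segment_directions,
    simulate_subject,
    ssa_denoise,
)
from eogadhd.preprocess import _normalize


def _rec(h, v=None, rate=500.0):
    h = np.asarray(h, dtype=float)
    v = h.copy() if v is None else np.asarray(v, dtype=float)
    return EogRecording(rate=rate, horizontal=h, vertical=v)


class TestDownsample:
    def test_length_shrinks_by_integer_factor(self):
        rec = downsample(_rec(np.random.default_rng(0).normal(size=500)))
        assert rec.n_samples == 20
        assert rec.rate == 20.0

    def test_dc_preserved(self):
        rec = downsample(_rec(np.full(1000, 3.25)))
        np.testing.assert_allclose(rec.horizontal, 3.25, rtol=1e-9)

    def test_passband_sine_amplitude_preserved(self):
        # 1 Hz unit sine is far below the 8 Hz cutoff
        t = np.arange(0, 10, 1 / 500)
        rec = downsample(_rec(np.sin(2 * np.pi * 1.0 * t)))
        assert abs(rec.horizontal.max() - 1.0) < 0.01

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(_rec(np.zeros(100), rate=30.0), target_rate=20.0)


class TestNormalize:
    def test_minmax_maps_to_unit_interval(self):
        rec = normalize_amplitude(_rec([2.0, 4.0, 6.0], [-3.0, 1.0, 1.0]))
        np.testing.assert_allclose(rec.horizontal, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(rec.vertical, [0.0, 1.0, 1.0])

    def test_constant_channel_maps_to_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            rec = normalize_amplitude(_rec([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(rec.horizontal, 0.0)

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            _normalize(np.array([]))

    @given(
        hnp.arrays(
            np.float64, st.integers(2, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        ).filter(lambda a: np.ptp(a) > 1e-6)
    )
    def test_idempotent(self, x):
        once = _normalize(x)
        np.testing.assert_allclose(_normalize(once), once, atol=1e-12)
        assert once.min() == 0.0 and once.max() == 1.0


class TestSsa:
    def test_completeness_identity_keeping_all_components(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200).cumsum()
        back = ssa_denoise(x, SsaConfig(window=20, components=20))
        np.testing.assert_allclose(back, x, rtol=1e-8, atol=1e-8 * np.abs(x).max())

    def test_denoises_linear_trend(self):
        rng = np.random.default_rng(1)
        clean = np.linspace(0.0, 1.0, 400)
        noisy = clean + rng.normal(0.0, 0.1, 400)
        den = ssa_denoise(noisy, SsaConfig(window=20, components=2))
        assert np.corrcoef(den, clean)[0, 1] > 0.99

    def test_energy_criterion_keeps_step_structure(self):
        # a step train must survive the default 95 % energy truncation
        x = np.zeros(400)
        x[50::100] = 1.0
        x = np.repeat(x.cumsum() % 2, 1)
        den = ssa_denoise(x, SsaConfig())
        assert np.corrcoef(den, x)[0, 1] > 0.95

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            ssa_denoise(np.zeros(30), SsaConfig(window=20))


class TestSegmentDirections:
    def test_exactly_twelve_sections(self, small_schedule):
        rec = simulate_subject(small_schedule, SubjectProfile(), seed=0, rate=500)
        segments = segment_directions(downsample(rec), small_schedule)
        assert len(segments.sections) == 12
        assert {s for s, _ in segments.sections} == {1, 2, 3}

    def test_sections_partition_each_stage(self, small_schedule):
        rec = simulate_subject(small_schedule, SubjectProfile(), seed=0, rate=500)
        segments = segment_directions(downsample(rec), small_schedule)
        for stage in (1, 2, 3):
            t0, t1 = small_schedule.stage_bounds(stage)
            total = sum(
                segments.section(stage, d).duration
                for d in ("left", "right", "up", "down")
            )
            assert total == pytest.approx(t1 - t0)
            idx = np.concatenate(
                [segments.section(stage, d).indices for d in ("left", "right", "up", "down")]
            )
            assert len(idx) == len(np.unique(idx))

    def test_channels_follow_direction_axis(self, small_schedule):
        rec = simulate_subject(small_schedule, SubjectProfile(), seed=0, rate=500)
        segments = segment_directions(downsample(rec), small_schedule)
        for (stage, d), sec in segments.sections.items():
            assert sec.channel == ("H" if d in ("left", "right") else "V")

    def test_missing_direction_yields_empty_flagged_section(self, small_schedule):
        from eogadhd import StimulusSchedule

        pruned = StimulusSchedule(
            events=tuple(e for e in small_schedule.events if e.direction != "up"),
            stage_durations=small_schedule.stage_durations,
        )
        rec = simulate_subject(small_schedule, SubjectProfile(), seed=0, rate=500)
        with pytest.warns(UserWarning):
            segments = segment_directions(downsample(rec), pruned)
        assert len(segments.section(1, "up").indices) == 0

    def test_short_recording_rejected(self, small_schedule):
        rec = _rec(np.zeros(100), rate=20.0)
        with pytest.raises(ValueError):
            segment_directions(rec, small_schedule)
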