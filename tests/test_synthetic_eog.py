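import numpy as np
import pytest
from scipy.special import expit

from eogkit.synthetic_eog import (
    FrontEndConfig,
    SaccadeSpec,
    ScenarioSpec,
    _blink_pulse,
    calibration_scenario,
    generate_recording,
    render_uv,
    saccade_series_scenario,
)

QUIET = dict(noise_sd_uv=0.0, drift_amplitude_uv=0.0, mains_amplitude_uv=0.0)


class TestFrontEndConfig:
    def test_max_total_gain_is_first_stage_times_pot_limit(self):
        fe = FrontEndConfig()
        assert fe.max_total_gain == 5000.0

    def test_second_stage_snaps_to_pot_grid(self):
        fe = FrontEndConfig(second_stage_gain=100.3)
        steps = fe.second_stage_gain / (250.0 / 255.0)
        assert steps == pytest.approx(round(steps))

    @pytest.mark.parametrize("bad", [{"second_stage_gain": 300.0}, {"sampling_hz": 105.0}, {"low_cutoff_hz": 40.0}])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            FrontEndConfig(**bad)


class TestScenarioValidation:
    def test_overlapping_events_rejected_with_description(self):
        with pytest.raises(ValueError, match="refractory"):
            ScenarioSpec(
                duration_s=5.0,
                saccades=[SaccadeSpec(1.0, 10.0, 0.0), SaccadeSpec(1.1, 10.0, 0.0)],
            )

    def test_blink_overlapping_saccade_rejected(self):
        with pytest.raises(ValueError, match="refractory"):
            ScenarioSpec(duration_s=5.0, saccades=[(1.0, 10.0, 0.0)], blinks=[(1.05, 2, 0.5)])

    def test_degenerate_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            ScenarioSpec(duration_s=0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(duration_s=5.0, noise_sd_uv=-1.0)

    def test_yaml_round_trip(self, tmp_path):
        spec = calibration_scenario(seed=9)
        p = spec.to_file(tmp_path / "scenario.yaml")
        back = ScenarioSpec.from_file(p)
        assert back == spec


class TestGroundTruthBookkeeping:
    def test_one_truth_entry_per_scheduled_event(self):
        spec = ScenarioSpec(
            duration_s=10.0,
            saccades=[(1.0, 10.0, 0.0), (3.0, 0.0, 20.0), (5.0, -10.0, 0.0), (7.0, 15.0, 15.0)],
            **QUIET,
        )
        _, truth = generate_recording(spec)
        assert len(truth.saccades) == 4
        assert len(truth.blinks) == 0
        assert all(0 <= s.index < truth.n_samples for s in truth.saccades)

    def test_blink_pulse_indices_follow_gap(self):
        spec = ScenarioSpec(duration_s=8.0, blinks=[(2.0, 3, 0.6)], **QUIET)
        _, truth = generate_recording(spec)
        (b,) = truth.blinks
        assert b.count == 3
        assert b.pulse_indices == [200, 260, 320]


class TestSignalShape:
    def test_zero_input_is_constant_up_to_quantization(self):
        spec = ScenarioSpec(duration_s=5.0, **QUIET)
        record, _ = generate_recording(spec)
        assert np.max(np.abs(record.horizontal)) <= 1.0
        assert np.max(np.abs(record.vertical)) <= 1.0

    def test_seeded_determinism_bit_identical(self):
        spec = ScenarioSpec(duration_s=5.0, saccades=[(1.0, 20.0, 0.0)], blinks=[(3.0, 2, 0.5)], seed=7)
        r1, t1 = generate_recording(spec)
        r2, t2 = generate_recording(spec)
        np.testing.assert_array_equal(r1.horizontal, r2.horizontal)
        np.testing.assert_array_equal(r1.vertical, r2.vertical)
        assert t1 == t2

    def test_saccade_component_linear_in_degrees(self):
        h1, _, _ = render_uv(ScenarioSpec(duration_s=4.0, saccades=[(1.0, 10.0, 0.0)], **QUIET))
        h2, _, _ = render_uv(ScenarioSpec(duration_s=4.0, saccades=[(1.0, 20.0, 0.0)], **QUIET))
        np.testing.assert_allclose(h2, 2.0 * h1, rtol=1e-12)

    def test_step_height_matches_sensitivity(self):
        spec = ScenarioSpec(duration_s=4.0, saccades=[(1.0, 20.0, 0.0)], **QUIET)
        h, v, _ = render_uv(spec)
        assert h[-1] == pytest.approx(spec.uv_per_degree * 20.0, rel=1e-6)
        assert np.max(np.abs(v)) == 0.0

    def test_high_pass_restores_baseline_after_held_gaze(self):
        # AC coupling: a sustained gaze deflection decays back toward zero
        spec = ScenarioSpec(duration_s=40.0, saccades=[(1.0, 40.0, 0.0)], **QUIET)
        record, _ = generate_recording(spec)
        peak = np.max(np.abs(record.horizontal))
        tail = np.mean(np.abs(record.horizontal[-300:]))
        assert tail < 0.05 * peak

    def test_default_amplitudes_within_physiological_range(self):
        # pre-amplifier peaks between 50 and 3500 uV for default settings
        spec = ScenarioSpec(duration_s=6.0, saccades=[(1.0, 40.0, 0.0)], blinks=[(3.0, 1, 0.5)], **QUIET)
        h, v, _ = render_uv(spec)
        assert 50.0 <= np.max(np.abs(h)) <= 3500.0
        assert 50.0 <= np.max(np.abs(v)) <= 3500.0


class TestBlinkSaccadeDiscrimination:
    def test_blink_rise_faster_than_saccade_transition(self):
        spec = ScenarioSpec(duration_s=4.0)
        t = np.linspace(0.0, 1.0, 100_000)
        blink = _blink_pulse(t, 0.2, 1.0, spec.blink_rise_s, spec.blink_duration_s)

        def rise_time(y, t):
            lo = t[np.argmax(y >= 0.1 * y.max())]
            hi = t[np.argmax(y >= 0.9 * y.max())]
            return hi - lo

        tau = spec.saccade_transition_s / 6.0
        step = expit((t - 0.5) / tau)
        assert rise_time(blink, t) < rise_time(step, t)

    def test_blink_over_while_saccade_step_persists(self):
        spec = ScenarioSpec(duration_s=4.0)
        t = np.linspace(0.0, 2.0, 200_000)
        blink = _blink_pulse(t, 0.2, 1.0, spec.blink_rise_s, spec.blink_duration_s)
        above = t[blink > 0.05]
        blink_duration = above[-1] - above[0]
        assert blink_duration <= 0.3
        # the saccadic deflection is still >90% of its height 1 s later
        tau = spec.saccade_transition_s / 6.0
        step = expit((t - 0.5) / tau)
        assert step[np.searchsorted(t, 1.5)] > 0.9


class TestScenarioBuilders:
    def test_saccade_series_pairs_sum_to_zero(self):
        spec = saccade_series_scenario(n_saccades=20, seed=4)
        total_h = sum(s.h_deg for s in spec.saccades)
        total_v = sum(s.v_deg for s in spec.saccades)
        assert total_h == pytest.approx(0.0, abs=1e-9)
        assert total_v == pytest.approx(0.0, abs=1e-9)
        assert len(spec.saccades) == 20

    def test_calibration_scenario_covers_both_channels(self):
        spec = calibration_scenario()
        hs = {abs(s.h_deg) for s in spec.saccades if s.h_deg}
        vs = {abs(s.v_deg) for s in spec.saccades if s.v_deg}
        assert hs == vs == {10.0, 20.0, 30.0, 40.0}
        assert len(spec.blinks) == 3
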