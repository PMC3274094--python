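import numpy as np
import pytest

from eogkit.cwt_filter import CWTConfig, cwt_single_scale
from eogkit.saccade_model import (
    CalibrationModel,
    CalibrationSegment,
    calibrate,
    detect_candidates,
    measure_variation,
    quantify,
)
from eogkit.synthetic_eog import ScenarioSpec, generate_recording


def step_segment(height, n=240, at=120, noise_sd=0.0, rng=None):
    x = np.zeros(n)
    x[at:] = height
    if noise_sd and rng is not None:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def linear_segments(k_true=0.1, angles=(10.0, 20.0, 30.0, 40.0), noise_sd=0.0, rng=None):
    segs = []
    for ch in ("h", "v"):
        for a in angles:
            segs.append(
                CalibrationSegment(
                    samples=step_segment(a / k_true, noise_sd=noise_sd, rng=rng),
                    angle_deg=a,
                    channel=ch,
                )
            )
    return segs


class TestQuantify:
    @pytest.mark.parametrize(
        "variation,k,expected",
        [(250.0, 0.1, 25.0), (0.0, 0.37, 0.0), (-100.0, 0.1, -10.0)],
    )
    def test_linear_model(self, variation, k, expected):
        assert quantify(variation, k) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quantify(np.nan, 0.1)


class TestMeasureVariation:
    def test_clean_step_recovers_height(self):
        x = step_segment(123.0)
        assert measure_variation(x, 120, 100.0) == pytest.approx(123.0)

    def test_near_edge_returns_none(self):
        x = step_segment(10.0, n=40, at=5)
        assert measure_variation(x, 5, 100.0) is None


class TestCalibrate:
    def test_exact_linear_data_recovers_k(self):
        # angles 10..40 deg against variations 100..400 units -> k = 0.1 deg/unit
        model = calibrate(linear_segments(k_true=0.1))
        assert model.k_h == pytest.approx(0.1, rel=1e-9)
        assert model.k_v == pytest.approx(0.1, rel=1e-9)

    def test_threshold_is_fraction_of_smallest_peak(self):
        model = calibrate(linear_segments(k_true=0.1), threshold_fraction=0.5)
        # smallest saccade: 100-unit step -> Haar peak 100*sqrt(60)/2
        expected = 0.5 * 100.0 * np.sqrt(60.0) / 2.0
        assert model.threshold_h == pytest.approx(expected, rel=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        # parameter recovery across 50 seeded replicates
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = calibrate(linear_segments(k_true=0.1, noise_sd=5.0, rng=rng))
            estimates.append(model.k_h)
        assert abs(np.median(estimates) - 0.1) / 0.1 < 0.05

    def test_single_angle_rejected(self):
        segs = [
            CalibrationSegment(step_segment(100.0), 10.0, ch) for ch in ("h", "v")
        ] * 2
        with pytest.raises(ValueError, match="distinct"):
            calibrate(segs)

    def test_zero_variance_rejected(self):
        segs = []
        for ch in ("h", "v"):
            for a in (10.0, 20.0):
                segs.append(CalibrationSegment(np.zeros(240), a, ch))
        with pytest.raises(ValueError):
            calibrate(segs)


class TestDetectCandidates:
    @pytest.fixture()
    def model(self):
        return CalibrationModel(
            k_h=0.1, k_v=0.1, threshold_h=100.0, threshold_v=100.0, refractory=20
        )

    def test_all_below_threshold_gives_empty_list(self, model, rng):
        x = rng.normal(0.0, 1.0, 400)
        coeffs = cwt_single_scale(x, CWTConfig())
        assert detect_candidates(coeffs, x, model, "h") == []

    def test_two_separated_saccades_in_index_order(self, model):
        x = np.zeros(800)
        x[200:] += 200.0
        x[500:] += 300.0
        coeffs = cwt_single_scale(x, CWTConfig())
        cands = detect_candidates(coeffs, x, model, "h")
        assert [c.index for c in cands] == [200, 500]
        assert cands[0].angle_deg == pytest.approx(20.0, abs=0.5)
        assert cands[1].angle_deg == pytest.approx(30.0, abs=0.5)

    def test_threshold_monotonicity(self, model, rng):
        x = np.cumsum(rng.normal(0.0, 30.0, 2000))
        coeffs = cwt_single_scale(x, CWTConfig())
        counts = []
        for thr in (50.0, 150.0, 400.0, 1000.0):
            m = CalibrationModel(
                k_h=0.1, k_v=0.1, threshold_h=thr, threshold_v=thr, refractory=20
            )
            counts.append(len(detect_candidates(coeffs, x, m, "h")))
        assert counts == sorted(counts, reverse=True)

    def test_single_synthetic_saccade_quantified_within_two_degrees(self, user_models, pipeline_cfg):
        spec = ScenarioSpec(duration_s=4.0, saccades=[(2.0, 20.0, 0.0)], seed=21)
        record, _ = generate_recording(spec)
        coeffs = cwt_single_scale(record.horizontal, pipeline_cfg.cwt)
        cands = detect_candidates(coeffs, record.horizontal, user_models.calibration, "h")
        assert len(cands) == 1
        assert cands[0].angle_deg == pytest.approx(20.0, abs=2.0)

    def test_monotone_in_amplitude(self, user_models, pipeline_cfg):
        # larger injected saccades yield larger estimates (noise off)
        estimates = []
        for deg in (10.0, 20.0, 30.0, 40.0):
            spec = ScenarioSpec(
                duration_s=4.0,
                saccades=[(2.0, deg, 0.0)],
                noise_sd_uv=0.0,
                drift_amplitude_uv=0.0,
                mains_amplitude_uv=0.0,
            )
            record, _ = generate_recording(spec)
            coeffs = cwt_single_scale(record.horizontal, pipeline_cfg.cwt)
            (cand,) = detect_candidates(coeffs, record.horizontal, user_models.calibration, "h")
            estimates.append(cand.angle_deg)
        assert estimates == sorted(estimates)


class TestCalibrationModelIO:
    def test_json_round_trip(self, tmp_path):
        m = CalibrationModel(k_h=0.1, k_v=0.2, threshold_h=50.0, threshold_v=60.0)
        p = m.to_json(tmp_path / "cal.json")
        assert CalibrationModel.from_json(p) == m

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(k_h=-0.1, k_v=0.1, threshold_h=1.0, threshold_v=1.0)
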