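"""Envelope computation, extrema detection and feature extraction."""

import numpy as np
import pytest

from emgsmile import (
    EventLabel,
    GeneratorConfig,
    PipelineConfig,
    SmileParams,
    activation_profile,
    compute_envelope,
    detect_extrema,
    extract_features,
    generate_recording,
)
from emgsmile.envelope_features import Envelope, TooShortError, features_to_frame


class TestComputeEnvelope:
    def test_constant_preserved(self):
        env = compute_envelope(np.full(10_000, 0.7), PipelineConfig())
        np.testing.assert_allclose(env.values, 0.7, atol=1e-9)
        assert env.frame_rate == pytest.approx(10.0)

    def test_rectified_sine_frames_are_two_over_pi(self):
        # closed form: mean of |sin| over whole cycles is 2/pi; sampled at
        # 100 points per cycle so the Riemann sum converges to it
        fs = 10_000.0
        t = np.arange(int(10 * fs)) / fs
        series = np.sin(2 * np.pi * 100.0 * t)
        env = compute_envelope(series, PipelineConfig(), sampling_rate_hz=fs)
        np.testing.assert_allclose(env.values, 2 / np.pi, atol=0.01)

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortError):
            compute_envelope(np.ones(3000), PipelineConfig())

    def test_envelope_nonnegative(self, rng):
        series = rng.normal(size=20_000) * np.linspace(0, 1, 20_000)
        env = compute_envelope(series, PipelineConfig())
        assert np.all(env.values >= 0)

    def test_apex_time_and_value_recovered_from_generator(self, clean_generator_config):
        rec, events, params = generate_recording(clean_generator_config, "p01", return_params=True)
        env = compute_envelope(rec.samples[:, 0], PipelineConfig())
        for ev, p in zip(events, params):
            f0, f1 = env.frame_of(ev.onset_s), env.frame_of(ev.offset_s)
            apex_frame = f0 + int(np.argmax(env.values[f0:f1]))
            n_on = round(p.onset_duration)
            true_apex_frame = env.frame_of(ev.onset_s + n_on / 10.0)
            assert abs(apex_frame - true_apex_frame) <= 3
            assert env.values[apex_frame] == pytest.approx(p.apex_amplitude, rel=0.10)


def _triangle_envelope(apex=2.0, rise=10, fall=10, pad=5):
    v = np.concatenate([
        np.zeros(pad),
        np.linspace(0, apex, rise + 1),
        np.linspace(apex, 0, fall + 1)[1:],
        np.zeros(pad),
    ])
    return Envelope(values=v, frame_rate=10.0, t0_s=0.0)


class TestDetectExtrema:
    def test_single_bump(self):
        env = _triangle_envelope()
        maxima, minima = detect_extrema(env)
        assert len(maxima) == 1
        assert maxima[0][0] == 15  # pad + rise
        assert len(minima) == 2
        assert minima[0][0] < maxima[0][0] < minima[1][0]

    def test_two_peak_profile(self):
        prof = activation_profile(SmileParams(10, 10, 2.0, 2, 0.3))
        env = Envelope(values=prof, frame_rate=10.0)
        maxima, minima = detect_extrema(env)
        assert len(maxima) == 2
        interior = [m for m in minima if maxima[0][0] < m[0] < maxima[1][0]]
        assert len(interior) == 1
        assert interior[0][1] == pytest.approx(1.4)

    def test_flat_envelope_has_no_maxima(self):
        env = Envelope(values=np.full(100, 0.3), frame_rate=10.0)
        maxima, minima = detect_extrema(env)
        assert maxima == [] and minima == []

    def test_alternation(self, rng):
        env = compute_envelope(rng.normal(size=60_000) * (1 + np.sin(np.linspace(0, 20, 60_000)) ** 2),
                               PipelineConfig())
        maxima, minima = detect_extrema(env)
        if maxima:
            seq = sorted([(f, "max") for f, _ in maxima] + [(f, "min") for f, _ in minima])
            kinds = [k for _, k in seq]
            assert kinds[0] == "min" and kinds[-1] == "min"
            assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))


class TestExtractFeatures:
    def _rows(self, env, smile_type="posed"):
        event = EventLabel("p01", smile_type, 0.0, env.n_frames / 10.0, "smile", smile_type)
        return extract_features(env, detect_extrema(env), [event])

    def test_symmetric_triangle_features(self):
        rows = self._rows(_triangle_envelope(apex=2.0, rise=10, fall=10))
        assert len(rows) == 1
        r = rows[0]
        assert r.apex_magnitude == pytest.approx(2.0)
        assert r.onset_duration == 10 and r.offset_duration == 10
        assert r.onset_magnitude_change == pytest.approx(2.0)
        assert r.offset_magnitude_change == pytest.approx(-2.0)
        assert r.onset_speed == pytest.approx(0.2)
        assert r.offset_speed == pytest.approx(-0.2)

    def test_sign_conventions(self, rng):
        env = compute_envelope(rng.normal(size=100_000) * (1 + 3 * np.sin(np.linspace(0, 30, 100_000)) ** 4),
                               PipelineConfig())
        event = EventLabel("p01", "spontaneous", 0.0, env.n_frames / 10.0, "smile", "spontaneous")
        rows = extract_features(env, detect_extrema(env), [event])
        assert rows, "expected at least one peak"
        for r in rows:
            assert r.onset_magnitude_change >= 0
            assert r.offset_magnitude_change <= 0
            assert r.onset_speed >= 0 and r.offset_speed <= 0
            # exact speed-magnitude-duration consistency
            assert r.onset_speed == pytest.approx(r.onset_magnitude_change / r.onset_duration, abs=1e-12)
            assert r.offset_speed == pytest.approx(r.offset_magnitude_change / r.offset_duration, abs=1e-12)

    def test_rows_per_event_equals_interior_maxima(self):
        prof = activation_profile(SmileParams(10, 10, 2.0, 2, 0.3))
        env = Envelope(values=np.concatenate([np.zeros(5), prof, np.zeros(5)]), frame_rate=10.0)
        rows = self._rows(env)
        maxima, _ = detect_extrema(env)
        assert len(rows) == len(maxima) == 2

    def test_event_without_interior_maximum_yields_no_rows(self):
        env = _triangle_envelope()
        event = EventLabel("p01", "posed", 0.1, 0.4, "smile", "posed")  # before the bump
        assert extract_features(env, detect_extrema(env), [event]) == []

    def test_scaling_component_scales_magnitudes_not_durations(self, rng):
        series = rng.normal(size=60_000) * (1 + 2 * np.sin(np.linspace(0, 10, 60_000)) ** 2)
        cfg = PipelineConfig()
        env1 = compute_envelope(series, cfg)
        env3 = compute_envelope(3.0 * series, cfg)
        event = EventLabel("p01", "posed", 0.0, env1.n_frames / 10.0, "smile", "posed")
        r1 = extract_features(env1, detect_extrema(env1), [event])
        r3 = extract_features(env3, detect_extrema(env3), [event])
        assert len(r1) == len(r3) > 0
        for a, b in zip(r1, r3):
            assert b.apex_magnitude == pytest.approx(3 * a.apex_magnitude, rel=1e-9)
            assert b.onset_magnitude_change == pytest.approx(3 * a.onset_magnitude_change, rel=1e-9)
            assert b.onset_speed == pytest.approx(3 * a.onset_speed, rel=1e-9)
            assert b.onset_duration == a.onset_duration
            assert b.offset_duration == a.offset_duration

    def test_generator_cohort_duration_recovery(self):
        # zero-noise single-peak smiles: extracted onset duration tracks the
        # configured mean within 15% (smoothing smears a bounded amount)
        means = {k: dict(v) for k, v in GeneratorConfig().type_means.items()}
        for t in means:
            means[t]["n_peaks"] = 1.0
        cfg = GeneratorConfig(n_producers=4, events_per_block=3, block_duration_s=90,
                              mixing_matrix=np.eye(4), line_noise_amp=0, drift_amp=0,
                              sensor_noise_sd=0, background_activation=0,
                              producer_effect_sd=0, within_producer_gap_fraction=0.0,
                              type_means=means, seed=29)
        pc = PipelineConfig()
        durations = {"posed": [], "spontaneous": []}
        for i in range(cfg.n_producers):
            rec, events = generate_recording(cfg, f"p{i:02d}")
            env = compute_envelope(rec.samples[:, 0], pc)
            rows = extract_features(env, detect_extrema(env), events)
            for r in rows:
                durations[r.smile_type].append(r.onset_duration)
        for t in durations:
            measured = np.mean(durations[t])
            assert measured == pytest.approx(cfg.type_means[t]["onset_duration"], rel=0.15)


def test_features_to_frame_columns():
    env = _triangle_envelope()
    event = EventLabel("p01", "posed", 0.0, env.n_frames / 10.0, "smile", "posed")
    df = features_to_frame(extract_features(env, detect_extrema(env), [event]))
    assert list(df.columns) == [
        "producer_id", "event_ref", "peak_index", "smile_type", "apex_mV",
        "onset_frames", "offset_frames", "onset_dmag_mV", "offset_dmag_mV",
        "onset_speed", "offset_speed",
    ]
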