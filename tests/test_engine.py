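"""Engine behavior: filtering, matching, rejection cascade, streaming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import hilbert

from bei import (
    EEGRecording,
    EngineConfig,
    SegmentResult,
    SynthSpec,
    bandpass_delta,
    gen_background,
    minute_bei,
    noise_ratio,
    normalize_unit_range,
    scan_segment,
    stream_bei,
    window_distance,
)
from bei.bei_engine import (
    DegenerateSegmentError,
    StreamingBEI,
    _filter_segment_with_context,
)

from conftest import blink_pulse


def sine_rec(freq, duration_s=10.0, fs=128.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return EEGRecording(amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandpassDelta:
    def test_in_band_passthrough(self):
        rec = sine_rec(2.5)
        out = bandpass_delta(rec)
        mid = slice(rec.n_samples // 4, -rec.n_samples // 4)
        assert np.abs(out.samples[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stop_band_attenuation(self):
        out = bandpass_delta(sine_rec(20.0))
        mid = slice(out.n_samples // 4, -out.n_samples // 4)
        assert np.abs(out.samples[mid]).max() < 0.10

    def test_dc_removed(self):
        rec = EEGRecording(np.full(1280, 5.0), 128.0)
        out = bandpass_delta(rec)
        assert np.abs(out.samples).max() < 1e-6

    def test_octave_attenuation(self):
        # >= 20 dB (factor 10) one octave outside [1, 4] Hz
        for f in (0.5, 8.0):
            out = bandpass_delta(sine_rec(f, duration_s=30.0))
            mid = slice(out.n_samples // 4, -out.n_samples // 4)
            assert np.abs(out.samples[mid]).max() < 0.1

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass_delta(sine_rec(2.0, duration_s=1.0))

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass_delta(sine_rec(2.0, fs=8.0))


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [([0, 2, 4], [-1, 0, 1]), ([-5, 5], [-1, 1]), ([1, 0, 3, 2], [-1 / 3, -1, 1, 1 / 3])],
    )
    def test_affine_map(self, raw, expected):
        np.testing.assert_allclose(normalize_unit_range(np.array(raw, float)), expected)

    def test_constant_segment_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            normalize_unit_range(np.full(10, 3.0))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50).filter(
        lambda v: max(v) > min(v)))
    @settings(deadline=None, max_examples=50)
    def test_order_preserved_and_bounded(self, values):
        out = normalize_unit_range(np.array(values))
        assert out.min() == pytest.approx(-1) and out.max() == pytest.approx(1)
        # monotone map: sorting by input leaves output non-decreasing
        order = np.argsort(np.array(values), kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestWindowDistance:
    def test_identity_and_polarity(self, tpl128):
        d_t, d_o = window_distance(tpl128.values, tpl128)
        assert d_t == 0.0
        d_t2, d_o2 = window_distance(-tpl128.values, tpl128)
        assert d_o2 == 0.0
        assert d_t2 == pytest.approx(np.mean(2 * np.abs(tpl128.values)))
        assert d_o == pytest.approx(d_t2)

    def test_constant_offset_is_the_distance(self, tpl128):
        d_t, _ = window_distance(tpl128.values + 0.1, tpl128)
        assert d_t == pytest.approx(0.1, abs=1e-12)

    def test_length_mismatch(self, tpl128):
        with pytest.raises(ValueError, match="length"):
            window_distance(np.zeros(10), tpl128)


class TestNoiseRatio:
    def test_constant_positive_not_noisy(self):
        assert noise_ratio(np.full(192, 3.0)) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_window_noisy(self):
        assert noise_ratio(np.zeros(192)) == np.inf

    def test_clean_oscillation_below_threshold(self):
        t = np.arange(192) / 128.0
        assert noise_ratio(np.sin(2 * np.pi * 2.5 * t)) < 1.0

    def test_transient_above_threshold(self):
        fs = 128.0
        rng = np.random.default_rng(2)
        w = 0.5 * rng.standard_normal(192)
        w[60:70] += 40.0  # electrode pop against a quiet background
        assert noise_ratio(w) > 1.0


class TestScanSegment:
    def test_tiled_template_saturates(self, tpl128, cfg):
        n = int(10 * 128)
        tiled = np.tile(tpl128.values, int(np.ceil(n / tpl128.n_samples)))[:n] * 20
        res = scan_segment(EEGRecording(tiled, 128.0), tpl128, cfg)
        assert res.valid and res.bei == 1.0
        assert res.matches >= res.nomatches

    def test_off_template_oscillation_scores_zero(self, tpl128, cfg):
        res = scan_segment(sine_rec(1.0, amp=30.0), tpl128, cfg)
        assert res.valid and res.bei == 0.0 and res.matches == 0

    def test_single_embedded_instance_matches(self, tpl128, cfg, quiet_background128):
        x = quiet_background128.samples.copy()
        i0 = int(4 * 128)
        x[i0 : i0 + tpl128.n_samples] += 4 * 5.0 * tpl128.values
        res = scan_segment(EEGRecording(x, 128.0), tpl128, cfg)
        assert res.valid and res.matches >= 1

    def test_two_artifact_bursts_reject_segment(self, tpl128, cfg, quiet_background128):
        y = quiet_background128.samples.copy()
        pulse = blink_pulse(128.0, 200.0)
        for t0 in (2.0, 7.0):
            i = int(t0 * 128)
            y[i : i + pulse.size] += pulse
        res = scan_segment(EEGRecording(y, 128.0), tpl128, cfg)
        assert res.rejected_windows > cfg.max_rejected_windows_per_segment
        assert not res.valid and res.bei is None

    def test_constant_segment_degenerate(self, tpl128, cfg):
        res = scan_segment(EEGRecording(np.full(1280, 3.0), 128.0), tpl128, cfg)
        assert not res.valid and res.reason == "degenerate"

    def test_wrong_length_rejected(self, tpl128, cfg):
        with pytest.raises(ValueError, match="samples"):
            scan_segment(sine_rec(2.0, duration_s=5.0), tpl128, cfg)

    def test_opposite_mode_leaves_far_windows_uncounted(self, tpl128):
        from bei import classify_window

        cfg_alt = EngineConfig(opposite_mode="opposite_counts_as_nomatch")
        cfg_def = EngineConfig()
        near_nothing = np.zeros(tpl128.n_samples) + 0.99  # far from +-template
        assert classify_window(near_nothing, tpl128, cfg_def) == "nomatch"
        assert classify_window(near_nothing, tpl128, cfg_alt) is None
        assert classify_window(-tpl128.values, tpl128, cfg_alt) == "nomatch"
        assert classify_window(tpl128.values, tpl128, cfg_alt) == "match"


# ---------------------------------------------------------------------------
# brute-force oracle: explicit per-window loop with interval bookkeeping


def oracle_scan(samples, fs, template, cfg, pre=None, post=None):
    """Reference scan: per-window formulas and interval lists, no vector tricks."""
    filt = _filter_segment_with_context(np.asarray(samples, float), fs, cfg, pre, post)
    if float(filt.max() - filt.min()) <= 1e-8 * max(
        1.0, float(np.max(samples) - np.min(samples))
    ):
        return None  # degenerate
    lo, hi = filt.min(), filt.max()
    norm = -1 + 2 * (filt - lo) / (hi - lo)
    env = np.abs(hilbert(filt))
    L = template.n_samples
    counted = {"match": [], "nomatch": []}
    rejected = []
    for i in range(norm.size - L + 1):
        e = env[i : i + L]
        m = e.mean()
        noisy = m == 0 or e.std() / m > cfg.noise_ratio_threshold
        if noisy:
            if not any(i < b and i + L > a for (a, b) in rejected):
                rejected.append((i, i + L))
            continue
        d = np.mean(np.abs(norm[i : i + L] - template.values))
        cls = "match" if d < cfg.match_threshold else "nomatch"
        if not any(i < b and i + L > a for (a, b) in counted[cls]):
            counted[cls].append((i, i + L))
    return len(counted["match"]), len(counted["nomatch"]), len(rejected)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_scan_matches_bruteforce(self, seed, tpl64, cfg):
        fs = 64.0
        spec = SynthSpec(duration_s=10, fs=fs, rms_uv=10, embed_rate=0,
                         artifact_rate=0, seed=seed)
        rec = gen_background(spec)
        x = rec.samples.copy()
        rng = np.random.default_rng(seed + 500)
        # mix in template instances and blink transients at random
        for _ in range(rng.integers(0, 3)):
            i = int(rng.uniform(0, x.size - tpl64.n_samples))
            x[i : i + tpl64.n_samples] += rng.uniform(2, 5) * 10 * tpl64.values
        for _ in range(rng.integers(0, 3)):
            pulse = blink_pulse(fs, rng.uniform(100, 300))
            i = int(rng.uniform(0, x.size - pulse.size))
            x[i : i + pulse.size] += pulse
        res = scan_segment(EEGRecording(x, fs), tpl64, cfg)
        expected = oracle_scan(x, fs, tpl64, cfg)
        assert expected is not None
        assert (res.matches, res.nomatches, res.rejected_windows) == expected


class TestMinuteBEI:
    def make(self, beis, n_invalid):
        segs = [SegmentResult(10.0 * i, 1, 1, 0, True, b) for i, b in enumerate(beis)]
        segs += [
            SegmentResult(10.0 * (len(beis) + i), 0, 0, 2, False, None, "too_many_rejected_windows")
            for i in range(n_invalid)
        ]
        return segs

    def test_median_of_valid(self, cfg):
        assert minute_bei(self.make([0.2, 0.4, 0.6], 3), cfg) == pytest.approx(0.4)

    def test_too_few_valid_is_missing(self, cfg):
        assert minute_bei(self.make([0.2, 0.4], 4), cfg) is None

    def test_all_valid_equal(self, cfg):
        assert minute_bei(self.make([0.5] * 6, 0), cfg) == 0.5

    def test_wrong_count_rejected(self, cfg):
        with pytest.raises(ValueError, match="segment results"):
            minute_bei(self.make([0.5] * 5, 0), cfg)


class TestStreaming:
    def clean_recording(self, duration_s, fs=128.0, seed=11):
        spec = SynthSpec(duration_s=duration_s, fs=fs, embed_rate=2.0,
                         artifact_rate=0.0, seed=seed)
        from bei import gen_recording
        rec, _ = gen_recording(spec, stream_template(fs))
        return rec

    def test_cadence_and_count(self, tpl128, cfg):
        rec = self.clean_recording(120.0)
        trace = stream_bei(rec, tpl128, cfg)
        np.testing.assert_allclose(trace.times_s, np.arange(60.0, 121.0, 10.0))
        assert len(trace.times_s) == 7
        assert np.all(np.isfinite(trace.values))

    def test_short_recording_empty_trace(self, tpl128, cfg):
        rec = self.clean_recording(50.0)
        trace = stream_bei(rec, tpl128, cfg)
        assert trace.times_s.size == 0

    def test_consecutive_minutes_share_segments(self, tpl128, cfg):
        rec = self.clean_recording(80.0)
        trace = stream_bei(rec, tpl128, cfg)
        # 3 emissions from 8 segments: every segment scanned exactly once
        assert len(trace.segment_log) == 8
        starts = [s.start_s for s in trace.segment_log]
        assert starts == [10.0 * k for k in range(8)]

    def test_chunked_equals_batch(self, tpl128, cfg):
        rec = self.clean_recording(150.0)
        batch = stream_bei(rec, tpl128, cfg)
        rng = np.random.default_rng(3)
        for _ in range(5):
            n_cuts = int(rng.integers(1, 40))
            cuts = np.sort(rng.choice(np.arange(1, rec.n_samples), n_cuts, replace=False))
            chunked = stream_bei(rec, tpl128, cfg, chunks=np.split(rec.samples, cuts))
            np.testing.assert_array_equal(batch.times_s, chunked.times_s)
            np.testing.assert_array_equal(batch.values, chunked.values)
            np.testing.assert_array_equal(batch.n_valid_segments, chunked.n_valid_segments)

    def test_push_after_finalize_rejected(self, tpl128, cfg):
        eng = StreamingBEI(128.0, tpl128, cfg)
        eng.push(np.zeros(100))
        eng.finalize()
        with pytest.raises(RuntimeError):
            eng.push(np.zeros(10))

    def test_trace_csv_round_trip(self, tpl128, cfg, tmp_path):
        rec = self.clean_recording(120.0)
        trace = stream_bei(rec, tpl128, cfg)
        p = tmp_path / "trace.csv"
        trace.to_csv(p)
        from bei import BEITrace

        back = BEITrace.from_csv(p)
        np.testing.assert_allclose(back.times_s, trace.times_s)
        np.testing.assert_allclose(back.values, trace.values)


def stream_template(fs):
    from bei import default_template

    return default_template(fs)


class TestEngineConfig:
    def test_defaults_are_study_constants(self, cfg):
        assert cfg.delta_band == (1.0, 4.0)
        assert (cfg.segment_s, cfg.window_s, cfg.cadence_s) == (10.0, 60.0, 10.0)
        assert cfg.template_ms == 1500.0
        assert cfg.match_threshold == 0.5
        assert cfg.noise_ratio_threshold == 1.0
        assert cfg.max_rejected_windows_per_segment == 1
        assert cfg.min_valid_segments_per_minute == 3

    def test_window_must_tile_segments(self):
        with pytest.raises(ValueError, match="multiple"):
            EngineConfig(window_s=65.0)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = EngineConfig(match_threshold=0.4)
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert EngineConfig.from_yaml(p) == cfg


class TestAdversarialBounds:
    """Every emitted BEI stays in [0, 1] whatever the input looks like."""

    @staticmethod
    def run(samples, fs=128.0):
        from bei import default_template

        trace = stream_bei(EEGRecording(samples, fs), default_template(fs), EngineConfig())
        finite = trace.values[np.isfinite(trace.values)]
        assert finite.size == 0 or (finite.min() >= 0.0 and finite.max() <= 1.0)
        return trace

    def test_constant_signal(self):
        self.run(np.full(128 * 70, 7.0))

    def test_spike_train(self):
        x = np.zeros(128 * 70)
        x[::64] = 1e4
        self.run(x)

    def test_clipped_square(self):
        t = np.arange(128 * 70) / 128.0
        self.run(np.sign(np.sin(2 * np.pi * 3 * t)) * 100)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=5)
    def test_random_heavy_tails(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_t(df=1.5, size=128 * 70) * 50
        x = np.clip(x, -500, 500)
        self.run(x)
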