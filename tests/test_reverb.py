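"""Filtering, envelope, noise-time, Schroeder integration and T60 estimation."""

import numpy as np
import pytest
from scipy import signal

from echowing import (
    Band,
    EnvelopeCurve,
    FilterSpec,
    NoDecayError,
    Recording,
    band_t60,
    bandpass_filter,
    estimate_noise_time,
    estimate_t60,
    min_stopband_attenuation_db,
    recording_t60,
    schroeder_curve,
    smoothed_envelope,
)
from echowing.synthetic import DecaySpec, gen_decay_recording
from echowing.types import SchroederCurve

FS = 625_000.0


def tone(freq, fs=FS, dur=0.02, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return Recording(samples=amp * np.cos(2 * np.pi * freq * t), fs=fs, tau_off=0.0)


class TestBandpassFilter:
    def test_design_constraints_enforced(self, band20k):
        with pytest.raises(ValueError):
            FilterSpec(band=band20k, fs=FS, stop_atten_db=60.0)
        with pytest.raises(ValueError):
            FilterSpec(band=Band.from_centre(300_000.0), fs=FS)

    def test_tone_at_centre_preserved(self, band20k):
        fspec = FilterSpec(band=band20k, fs=FS)
        rec = tone(band20k.fc, amp=0.7)
        out = bandpass_filter(rec, fspec)
        mid = out.samples[len(out.samples) // 4: len(out.samples) // 2]
        assert np.max(np.abs(mid)) == pytest.approx(0.7, rel=1e-2)

    def test_tone_below_band_attenuated_80db(self, band20k):
        fspec = FilterSpec(band=band20k, fs=FS)
        rec = tone(0.5 * band20k.fl)
        out = bandpass_filter(rec, fspec)
        mid = out.samples[len(out.samples) // 4: len(out.samples) // 2]
        atten = -20 * np.log10(np.max(np.abs(mid)))
        assert atten >= 80.0

    def test_min_stopband_attenuation_meets_design(self, band20k):
        assert min_stopband_attenuation_db(FilterSpec(band=band20k, fs=FS)) >= 80.0

    def test_measured_transfer_function_matches_design(self, band20k):
        """White noise through the filter: Welch-estimated response vs freqz."""
        fspec = FilterSpec(band=band20k, fs=FS)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(2**19)
        rec = Recording(samples=x, fs=FS, tau_off=0.0)
        y = bandpass_filter(rec, fspec).samples
        f, pxx = signal.welch(x, fs=FS, nperseg=8192)
        _, pyy = signal.welch(y, fs=FS, nperseg=8192)
        measured_db = 10 * np.log10(pyy / pxx)
        _, h = signal.freqz(fspec.design(), worN=f, fs=FS)
        design_db = 20 * np.log10(np.abs(h) + 1e-12)
        in_band = (f >= band20k.fl) & (f <= band20k.fh)
        assert np.max(np.abs(measured_db[in_band] - design_db[in_band])) < 1.0

    def test_group_delay_compensated(self, band20k):
        """A burst ending at tau_off stays aligned after filtering."""
        fs = FS
        n = int(0.03 * fs)
        t = np.arange(n) / fs
        tau_off = 0.02
        x = np.cos(2 * np.pi * band20k.fc * t) * (t < tau_off)
        rec = Recording(samples=x, fs=fs, tau_off=tau_off)
        out = bandpass_filter(rec, FilterSpec(band=band20k, fs=fs))
        env = np.abs(signal.hilbert(out.samples))
        # envelope half-amplitude point should sit within 0.2 ms of tau_off
        half = np.argmin(np.abs(env - 0.5 * env[: n // 2].max()))
        assert abs(half / fs - tau_off) < 2e-4


class TestEnvelope:
    def test_cosine_amplitude_recovered(self):
        rec = tone(50_000.0, amp=0.8)
        env = smoothed_envelope(rec, window_samples=625)
        core = env.values[2000:-2000]
        assert np.median(core) == pytest.approx(0.8, rel=1e-2)

    def test_decaying_tone_slope(self):
        """Exponentially decaying tone: log-envelope slope matches the decay
        constant within 2%."""
        fs = FS
        k = 200.0  # amplitude decay rate, 1/s
        t = np.arange(int(0.02 * fs)) / fs
        rec = Recording(
            samples=np.exp(-k * t) * np.cos(2 * np.pi * 50_000.0 * t),
            fs=fs, tau_off=0.0,
        )
        env = smoothed_envelope(rec, window_samples=125)
        sel = slice(2000, -2000)
        slope = np.polyfit(t[sel], np.log(env.values[sel]), 1)[0]
        assert slope == pytest.approx(-k, rel=0.02)

    def test_window_validation(self):
        rec = tone(50_000.0, dur=0.001)
        with pytest.raises(ValueError):
            smoothed_envelope(rec, window_samples=0)
        with pytest.raises(ValueError):
            smoothed_envelope(rec, window_samples=10**6)


def synth_envelope(k, floor, fs=50_000.0, dur=0.2, tau_off=0.01):
    """Deterministic envelope: steady until tau_off, then exp decay + floor."""
    t = np.arange(int(dur * fs)) / fs
    decay = np.where(t < tau_off, 1.0, np.exp(-k * (t - tau_off)))
    return EnvelopeCurve(values=np.sqrt(decay**2 + floor**2), fs=fs)


class TestNoiseTime:
    def test_constructed_intersection_recovered(self):
        # decay at 20log10(e)*k dB/s meets floor at t* = tau_off - ln(floor)/k
        k, floor = 120.0, 10 ** (-50 / 20)
        env = synth_envelope(k, floor)
        t_star = 0.01 + -np.log(floor) / k
        tau_N = estimate_noise_time(env, tau_off=0.01)
        assert tau_N == pytest.approx(t_star, rel=0.2)

    def test_noiseless_decay_returns_record_end(self):
        env = synth_envelope(120.0, floor=0.0, dur=0.1)
        assert estimate_noise_time(env, tau_off=0.01) == pytest.approx(
            env.times[-1], rel=1e-6
        )

    def test_stationary_noise_raises_no_decay(self):
        rng = np.random.default_rng(0)
        env = EnvelopeCurve(values=0.1 + 0.01 * rng.random(5000), fs=50_000.0)
        with pytest.raises(NoDecayError):
            estimate_noise_time(env, tau_off=0.01)


class TestSchroederCurve:
    def test_normalised_and_monotone(self):
        env = synth_envelope(120.0, floor=1e-4)
        curve = schroeder_curve(env, tau_off=0.01, tau_N=0.15)
        assert curve.level_db[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(curve.level_db) <= 1e-12)

    def test_pure_exponential_closed_form_slope(self):
        """E = exp(-kt): Schroeder slope is -20k/ln(10) dB/s within 0.5%."""
        k = 150.0
        fs = 50_000.0
        t = np.arange(int(0.4 * fs)) / fs
        env = EnvelopeCurve(values=np.exp(-k * t), fs=fs)
        curve = schroeder_curve(env, tau_off=0.0, tau_N=t[-1])
        t60 = estimate_t60(curve)
        expected_slope = -20.0 * k / np.log(10.0)
        assert curve.slope_A == pytest.approx(expected_slope, rel=0.005)
        assert t60 == pytest.approx(-60.0 / expected_slope, rel=0.005)

    def test_slope_invariant_to_truncation_point(self):
        """Halving tau_N on a pure exponential leaves the slope within 1%."""
        k = 150.0
        fs = 50_000.0
        t = np.arange(int(0.4 * fs)) / fs  # level spans ~520 dB
        env = EnvelopeCurve(values=np.exp(-k * t), fs=fs)
        full = schroeder_curve(env, tau_off=0.0, tau_N=t[-1])
        half = schroeder_curve(env, tau_off=0.0, tau_N=t[-1] / 2)
        estimate_t60(full), estimate_t60(half)
        assert half.slope_A == pytest.approx(full.slope_A, rel=0.01)

    def test_invalid_interval_rejected(self):
        env = synth_envelope(120.0, floor=1e-4)
        with pytest.raises(ValueError):
            schroeder_curve(env, tau_off=0.05, tau_N=0.02)


class TestEstimateT60:
    def test_exact_line(self):
        t = np.linspace(0.0, 0.05, 200)
        curve = SchroederCurve(level_db=-1000.0 * t, times=t, tau_N=0.05)
        assert estimate_t60(curve) == pytest.approx(0.060, rel=1e-9)

    def test_time_dilation_scaling(self):
        spec = DecaySpec(
            band=Band.from_centre(20_000.0), t60_true=0.02, steady_dur=0.01,
            record_dur=0.2, noise_floor_db=-60, seed=3,
        )
        rec = gen_decay_recording(spec, FS)
        band = Band.from_centre(20_000.0)
        t1, _, _ = recording_t60(rec, band)
        # present the same samples at half the sampling rate: time dilation x2
        dil = Recording(samples=rec.samples, fs=FS / 2, tau_off=rec.tau_off * 2)
        band_d = Band.from_centre(10_000.0)  # frequencies scale with fs
        t2, _, _ = recording_t60(dil, band_d)
        assert t2 == pytest.approx(2 * t1, rel=1e-3)

    def test_nonnegative_slope_raises(self):
        t = np.linspace(0.0, 0.05, 200)
        curve = SchroederCurve(level_db=np.zeros_like(t), times=t, tau_N=0.05)
        with pytest.raises(NoDecayError):
            estimate_t60(curve)


class TestBandT60:
    def test_identical_recordings_average_to_single_estimate(self, band20k):
        spec = DecaySpec(
            band=band20k, t60_true=0.025, steady_dur=0.015, record_dur=0.25,
            noise_floor_db=-60, seed=1,
        )
        rec = gen_decay_recording(spec, FS)
        single, _, _ = recording_t60(rec, band20k)
        mean = band_t60([rec] * 4, band20k)
        assert mean.t60 == pytest.approx(single, rel=1e-12)
        assert mean.n_positions == 4

    def test_arithmetic_mean_of_positions(self, band20k):
        recs = []
        for seed, t60 in ((1, 0.02), (2, 0.03)):
            spec = DecaySpec(
                band=band20k, t60_true=t60, steady_dur=0.015, record_dur=0.3,
                noise_floor_db=-70, seed=seed,
            )
            recs.append(gen_decay_recording(spec, FS))
        singles = [recording_t60(r, band20k)[0] for r in recs]
        mean = band_t60(recs, band20k)
        assert mean.t60 == pytest.approx(np.mean(singles), rel=1e-12)

    def test_failing_position_excluded_with_warning(self, band20k, caplog):
        spec = DecaySpec(
            band=band20k, t60_true=0.025, steady_dur=0.015, record_dur=0.25,
            noise_floor_db=-60, seed=1,
        )
        good = gen_decay_recording(spec, FS)
        rng = np.random.default_rng(0)
        flat = Recording(
            samples=rng.standard_normal(good.samples.size) * 0.01,
            fs=FS, tau_off=good.tau_off,
        )
        with caplog.at_level("WARNING", logger="echowing"):
            mean = band_t60([good, flat], band20k)
        assert mean.n_positions == 1
        assert any("excluded" in r.message for r in caplog.records)
        with pytest.raises(NoDecayError):
            band_t60([flat], band20k)
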