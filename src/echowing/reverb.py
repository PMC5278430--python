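"""Reverberation-time estimation from steady-state decay recordings.

Processing chain for one 1/3-octave band:

1. Kaiser-window linear-phase FIR bandpass (stopband attenuation
   >= 80 dB), with the group delay compensated so the sound-offset time
   is preserved.
2. Envelope by the magnitude of the analytic signal (Hilbert transform),
   smoothed with a centred moving average (default 625 samples, i.e.
   1 ms at 625 kHz sampling).
3. Noise-crossing time ``tau_N`` by an iterative decay-line /
   noise-floor intersection (Lundeby-style).
4. Backward (Schroeder) integration of the squared smoothed envelope
   between the sound offset ``tau_off`` and ``tau_N``, giving a
   monotone decay curve ``L`` in dB normalised to 0 dB at the offset.
5. Least-squares line ``L'(t) = A t + B`` over the evaluation range and
   extrapolation to -60 dB: ``T60 = -(60 + B) / A`` with the time
   origin at the offset.

The Schroeder integral is evaluated on the squared envelope by default
(reverberation is an energy-decay concept); an amplitude variant is
available through ``schroeder_curve(..., square=False)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import Band, EnvelopeCurve, Recording, ReverbMeasurement, SchroederCurve

logger = logging.getLogger("echowing")

#: Default smoothing window: 625 samples = 1 ms at fs = 625 kHz.
DEFAULT_SMOOTH_SAMPLES = 625

#: Lower limit of the regression evaluation range, dB re offset.
REGRESSION_FLOOR_DB = -45.0


class NoDecayError(RuntimeError):
    """Raised when a recording contains no detectable decay."""


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-window FIR bandpass design for one analysis band.

    ``transition_frac`` sets the transition width as a fraction of the
    lower band edge; the cutoffs are widened by half the transition so
    the nominal passband [fl, fh] lies fully inside the -stop_atten
    design passband.
    """

    band: Band
    fs: float
    stop_atten_db: float = 80.0
    transition_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.stop_atten_db < 80:
            raise ValueError("stopband attenuation must be at least 80 dB")
        if not (0 < self.transition_frac < 0.5):
            raise ValueError("transition_frac must lie in (0, 0.5)")
        if self.band.fh >= self.fs / 2:
            raise ValueError(
                f"band edge {self.band.fh} Hz at or above Nyquist {self.fs / 2} Hz"
            )

    @property
    def transition_hz(self) -> float:
        return self.transition_frac * self.band.fl

    def design(self) -> np.ndarray:
        """Return the FIR taps (odd length, linear phase)."""
        nyq = self.fs / 2.0
        numtaps, beta = signal.kaiserord(self.stop_atten_db, self.transition_hz / nyq)
        numtaps |= 1  # odd length: integer group delay, type-I FIR
        lo = self.band.fl - self.transition_hz / 2.0
        hi = self.band.fh + self.transition_hz / 2.0
        if lo <= 0 or hi >= nyq:
            raise ValueError("transition band exceeds [0, Nyquist]")
        return signal.firwin(
            numtaps, [lo, hi], window=("kaiser", beta), pass_zero=False, fs=self.fs
        )

    def stopband_edges(self) -> tuple[float, float]:
        """(upper edge of low stopband, lower edge of high stopband) in Hz."""
        return (
            self.band.fl - self.transition_hz,
            self.band.fh + self.transition_hz,
        )


def filter_attenuation_db(
    fspec: FilterSpec, n_grid: int = 20000
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response of the designed filter in dB on a dense grid."""
    taps = fspec.design()
    w, h = signal.freqz(taps, worN=n_grid, fs=fspec.fs)
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(np.abs(h))
    return w, mag_db


def min_stopband_attenuation_db(fspec: FilterSpec, n_grid: int = 20000) -> float:
    """Minimum attenuation (positive dB) over both stopband regions."""
    w, mag_db = filter_attenuation_db(fspec, n_grid)
    lo_edge, hi_edge = fspec.stopband_edges()
    stop = (w <= lo_edge) | (w >= hi_edge)
    return float(-np.max(mag_db[stop]))


def bandpass_filter(rec: Recording, fspec: FilterSpec) -> Recording:
    """Apply the band filter forward-only and compensate the group delay.

    The FIR is linear phase with integer delay (numtaps-1)/2, so shifting
    the output left by that many samples realigns the decay with the
    recorded ``tau_off``. The tail is zero-padded back to full length.
    """
    if not np.isclose(rec.fs, fspec.fs):
        raise ValueError(f"fs mismatch: recording {rec.fs}, filter {fspec.fs}")
    taps = fspec.design()
    delay = (len(taps) - 1) // 2
    # fftconvolve 'full' then crop == lfilter, but much faster for long FIRs
    y = signal.fftconvolve(rec.samples, taps, mode="full")[: rec.samples.size + delay]
    y = y[delay:]
    return Recording(samples=y, fs=rec.fs, tau_off=rec.tau_off, position_id=rec.position_id)


def smoothed_envelope(
    rec: Recording, window_samples: int = DEFAULT_SMOOTH_SAMPLES
) -> EnvelopeCurve:
    """Hilbert-transform envelope smoothed with a centred moving average."""
    if rec.samples.size == 0:
        raise ValueError("empty signal")
    if not (1 <= window_samples < rec.samples.size):
        raise ValueError("window_samples must be >= 1 and shorter than the signal")
    from scipy.fft import next_fast_len
    from scipy.ndimage import uniform_filter1d

    n = rec.samples.size
    env = np.abs(signal.hilbert(rec.samples, N=next_fast_len(n))[:n])
    if window_samples > 1:
        env = uniform_filter1d(env, size=window_samples, mode="nearest")
    return EnvelopeCurve(values=np.maximum(env, 0.0), fs=rec.fs)


def _env_level_db(env: EnvelopeCurve, floor: float = 1e-300) -> np.ndarray:
    """Energy level 20*log10 |E| of the envelope, guarded against log(0)."""
    return 20.0 * np.log10(np.maximum(env.values, floor))


def estimate_noise_time(
    env: EnvelopeCurve,
    tau_off: float,
    *,
    margin_db: float = 5.0,
    tail_frac: float = 0.1,
    max_iter: int = 5,
) -> float:
    """Time where the regressed late decay meets the noise floor.

    Iterative scheme in the spirit of Lundeby's truncation-point method:
    the noise level is first taken from the last ``tail_frac`` of the
    record, a line is regressed on the decay between the offset level
    and ``margin_db`` above the noise, their intersection gives a
    provisional crossing, and the noise estimate is refreshed from the
    samples beyond the crossing plus a safety margin.  Converges in a
    handful of iterations on exponential decays.

    Returns the recording end time when the decay never reaches the
    noise floor (noiseless convention); raises :class:`NoDecayError`
    when no decaying segment is detectable.
    """
    t = env.times
    n_off = int(round(tau_off * env.fs))
    if n_off >= env.values.size - 2:
        raise NoDecayError("no samples after the sound offset")
    level = _env_level_db(env)
    end_time = t[-1]

    # decimate the level curve for regression robustness/speed
    step = max(1, (env.values.size - n_off) // 2000)
    idx = np.arange(n_off, env.values.size, step)
    tt, ll = t[idx], level[idx]

    l_off = ll[0]
    noise = np.median(ll[int(len(ll) * (1 - tail_frac)):])
    if l_off - noise < 10.0:
        raise NoDecayError(
            "no decay: offset level within 10 dB of the noise floor"
        )
    # a stationary floor is flat: if the tail is still decaying there is
    # no noise floor to cross and the whole record is usable
    prev = np.median(ll[int(len(ll) * (1 - 2 * tail_frac)): int(len(ll) * (1 - tail_frac))])
    if prev - noise > margin_db:
        return end_time

    tau_N = end_time
    for _ in range(max_iter):
        # contiguous decay segment: from the offset until the level first
        # reaches margin_db above the noise floor (late noise excursions
        # must not enter the fit — their time leverage wrecks the slope)
        below = np.nonzero(ll <= noise + margin_db)[0]
        if below.size == 0:
            # decay never reaches the noise floor: noiseless convention
            return end_time
        first = below[0]
        sel = (ll[: first + 1] <= l_off - 1.0) & (tt[: first + 1] > tau_off)
        if sel.sum() < 5:
            break
        A, B = np.polyfit(tt[: first + 1][sel], ll[: first + 1][sel], 1)
        if A >= 0:
            raise NoDecayError("no decay: late envelope slope is nonnegative")
        crossing = (noise - B) / A
        tau_N_new = float(np.clip(crossing, tau_off + 1.0 / env.fs, end_time))
        # refresh the noise estimate from beyond the crossing + safety margin
        t_safe = tau_N_new + margin_db / -A
        tail = ll[tt >= t_safe]
        noise_new = np.median(tail) if tail.size >= 5 else noise
        if abs(tau_N_new - tau_N) < 1.0 / env.fs:
            tau_N = tau_N_new
            break
        tau_N, noise = tau_N_new, noise_new

    if tau_N >= end_time * (1 - 1e-9):
        return end_time
    return float(tau_N)


def schroeder_curve(
    env: EnvelopeCurve, tau_off: float, tau_N: float, *, square: bool = True
) -> SchroederCurve:
    """Backward-integrate the (squared) smoothed envelope to a decay curve.

    ``L(t) = 10 log10( int_t^{tau_N} Es^2 / int_{tau_off}^{tau_N} Es^2 )``
    evaluated on the sample grid; by construction ``L(tau_off) = 0`` and
    ``L`` is non-increasing.
    """
    if not tau_off < tau_N:
        raise ValueError("tau_off must precede tau_N")
    n0 = int(round(tau_off * env.fs))
    n1 = min(int(round(tau_N * env.fs)), env.values.size)
    seg = env.values[n0:n1]
    if seg.size < 2:
        raise ValueError("fewer than two samples between tau_off and tau_N")
    e = seg**2 if square else seg
    total = e.sum()
    if total <= 0:
        raise ValueError("zero energy between tau_off and tau_N")
    tail = np.cumsum(e[::-1])[::-1]
    level = 10.0 * np.log10(tail / total)
    times = (n0 + np.arange(seg.size)) / env.fs
    return SchroederCurve(level_db=level, times=times, tau_N=float(tau_N))


def estimate_t60(curve: SchroederCurve, *, floor_db: float = REGRESSION_FLOOR_DB) -> float:
    """Reverberation time by linear regression of the Schroeder curve.

    The line ``L'(t) = A t + B`` (time origin at the offset) is fitted
    between 0 dB and ``max(L(tau_N), floor_db)`` and extrapolated to
    -60 dB: ``T60 = -(60 + B) / A``.  The -45 dB default floor uses as
    much of the decay as possible (a wider range suppresses the
    realisation noise of a single band-limited decay) while excluding
    the downward-bent tail near ``tau_N`` where truncation and noise
    energy distort the integral; it presumes the decay spans at least
    ~50 dB above the noise floor.
    """
    if curve.level_db.size < 10:
        raise ValueError("need at least 10 samples on the Schroeder curve")
    lower = max(float(curve.level_db[-1]), floor_db)
    sel = curve.level_db >= lower
    if sel.sum() < 10:
        sel = np.ones_like(curve.level_db, dtype=bool)
    t_rel = curve.times[sel] - curve.times[0]
    A, B = np.polyfit(t_rel, curve.level_db[sel], 1)
    if A >= 0:
        raise NoDecayError("no decay: fitted Schroeder slope is nonnegative")
    curve.slope_A, curve.intercept_B = float(A), float(B)
    return float(-(60.0 + B) / A)


def recording_t60(
    rec: Recording,
    band: Band,
    *,
    stop_atten_db: float = 80.0,
    transition_frac: float = 0.1,
    window_samples: int = DEFAULT_SMOOTH_SAMPLES,
) -> tuple[float, float, float]:
    """Full single-position chain; returns (t60, tau_N, slope dB/s)."""
    fspec = FilterSpec(
        band=band, fs=rec.fs, stop_atten_db=stop_atten_db,
        transition_frac=transition_frac,
    )
    filtered = bandpass_filter(rec, fspec)
    env = smoothed_envelope(filtered, window_samples)
    tau_N = estimate_noise_time(env, rec.tau_off)
    curve = schroeder_curve(env, rec.tau_off, tau_N)
    t60 = estimate_t60(curve)
    return t60, tau_N, float(curve.slope_A)


def band_t60(
    recordings: list[Recording], band: Band, fs: float | None = None, **kwargs
) -> ReverbMeasurement:
    """Spatial average of per-position T60 estimates for one band.

    Positions whose estimation fails are excluded with a logged warning;
    the measurement errors out only if every position fails.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    estimates = []
    for rec in recordings:
        if fs is not None and not np.isclose(rec.fs, fs):
            raise ValueError(f"recording {rec.position_id} has fs {rec.fs} != {fs}")
        try:
            t60, _, _ = recording_t60(rec, band, **kwargs)
            estimates.append(t60)
        except (NoDecayError, ValueError) as exc:
            logger.warning("position %s excluded: %s", rec.position_id, exc)
    if not estimates:
        raise NoDecayError("T60 estimation failed at every microphone position")
    return ReverbMeasurement(
        band=band, t60=float(np.mean(estimates)), n_positions=len(estimates)
    )
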