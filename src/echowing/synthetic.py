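"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the laboratory inputs:

* band-limited steady-state decay recordings with a prescribed
  reverberation time and a stationary noise floor (the chamber
  recordings);
* two-class wing-silhouette images on a white background with an exact
  rendered pixel count (the specimen photographs);
* balanced long-format absorption tables with the study's
  9-preparation x 6-set x 8-band repeated-measures design.

The decay stimulus is Gaussian noise band-limited with a Butterworth
filter (deliberately a different filter family from the Kaiser FIR used
by the analysis chain, so generation and estimation share no code
path), multiplied after the offset by the amplitude law
``exp(-3 ln(10) (t - tau_off) / T60)`` so the energy envelope decays at
exactly 60/T60 dB/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .absorption import invert_wing_alpha
from .types import (
    AirProperties,
    Band,
    ChamberSpec,
    RM_GROUPS,
    RMDataset,
    Recording,
)

#: Amplitude decay constant: 60 dB energy drop over one T60.
AMP_DECAY_LN = 3.0 * np.log(10.0)  # = 6.9078 / T60 per second

#: Default position-to-position reverberation-time jitter (fraction,
#: uniform), standing in for residual non-diffuseness of the chamber.
DEFAULT_T_JITTER = 0.02


@dataclass(frozen=True)
class DecaySpec:
    """Parameters of one synthetic steady-state decay recording."""

    band: Band
    t60_true: float
    steady_dur: float = 0.015
    record_dur: float = 0.25
    noise_floor_db: float = -60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t60_true <= 0:
            raise ValueError("t60_true must be positive")
        if self.steady_dur <= 0 or self.record_dur <= self.steady_dur:
            raise ValueError("need 0 < steady_dur < record_dur")
        if self.noise_floor_db >= 0:
            raise ValueError("noise floor must be below the steady-state level")


def _bandlimited_noise(
    rng: np.random.Generator, n: int, band: Band, fs: float
) -> np.ndarray:
    """Unit-variance white noise band-limited to the analysis band."""
    sos = signal.butter(4, [band.fl, band.fh], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def gen_decay_recording(spec: DecaySpec, fs: float) -> Recording:
    """Synthesize a steady-state decay with a stationary noise floor.

    The ensemble energy envelope is flat before ``tau_off =
    steady_dur`` and decays at 60/t60_true dB/s afterwards; an
    independent band-limited noise floor sits ``noise_floor_db`` below
    the steady-state level.  Bit-identical output for a fixed seed.
    """
    if fs <= 2 * spec.band.fh:
        raise ValueError(
            f"fs={fs} must exceed twice the upper band edge {spec.band.fh}"
        )
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.record_dur * fs))
    t = np.arange(n) / fs

    sig = _bandlimited_noise(rng, n, spec.band, fs)
    noise = _bandlimited_noise(rng, n, spec.band, fs)

    rms_sig = np.sqrt(np.mean(sig**2))
    sig /= rms_sig
    noise *= 10.0 ** (spec.noise_floor_db / 20.0) / np.sqrt(np.mean(noise**2))

    envelope = np.ones(n)
    decaying = t >= spec.steady_dur
    envelope[decaying] = np.exp(
        -AMP_DECAY_LN * (t[decaying] - spec.steady_dur) / spec.t60_true
    )
    return Recording(
        samples=sig * envelope + noise,
        fs=fs,
        tau_off=spec.steady_dur,
        position_id=f"seed{spec.seed}",
    )


@dataclass
class PairedChamberTruth:
    """Ground truth attached to a synthetic paired-measurement set."""

    T0: float
    T1: float
    alpha0_true: float
    alphaw_true: float
    Sw: float
    band: Band


def gen_paired_chamber_recordings(
    chamber: ChamberSpec,
    air: AirProperties,
    band: Band,
    alpha0_true: float,
    alphaw_true: float,
    Sw: float,
    n_pos_empty: int = 27,
    n_pos_wings: int = 4,
    fs: float = 625_000.0,
    seed: int = 0,
    *,
    t_jitter: float = DEFAULT_T_JITTER,
    noise_floor_db: float = -60.0,
    steady_dur: float = 0.015,
    decay_t60_mult: float = 7.0,
) -> tuple[list[Recording], list[Recording], PairedChamberTruth]:
    """Emit empty-chamber and wings-in recordings with known absorption.

    The empty-chamber reverberation time ``T0`` is obtained by inverting
    the Sabine relation at ``alpha0_true``; ``T1`` follows from
    inverting the difference form at ``alphaw_true``.  Each microphone
    position receives an independent decay realisation whose T60 is
    jittered by a uniform fraction ``+-t_jitter`` around the nominal
    value, mimicking residual non-diffuseness.
    """
    if alpha0_true <= 0:
        raise ValueError("alpha0_true must be positive")
    T0, T1 = invert_wing_alpha(chamber, band, alpha0_true, alphaw_true, Sw, air)
    rng = np.random.default_rng(seed)

    def _positions(T: float, count: int, tag: str) -> list[Recording]:
        recs = []
        record_dur = steady_dur + max(decay_t60_mult * T, 0.05)
        for i in range(count):
            t_pos = T * (1.0 + rng.uniform(-t_jitter, t_jitter))
            spec = DecaySpec(
                band=band,
                t60_true=t_pos,
                steady_dur=steady_dur,
                record_dur=record_dur,
                noise_floor_db=noise_floor_db,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = gen_decay_recording(spec, fs)
            rec.position_id = f"{tag}{i}"
            recs.append(rec)
        return recs

    empty = _positions(T0, n_pos_empty, "empty")
    wings = _positions(T1, n_pos_wings, "wings")
    truth = PairedChamberTruth(
        T0=T0, T1=T1, alpha0_true=alpha0_true, alphaw_true=alphaw_true,
        Sw=Sw, band=band,
    )
    return empty, wings, truth


# ---------------------------------------------------------------------------
# Wing images

@dataclass
class SyntheticWingImage:
    """Rendered wing-set photograph with exact pixel-count truth."""

    image: np.ndarray        # float64 in [0, 1], white background
    mask: np.ndarray         # bool, True on wing pixels
    n_wing_px: int
    wing_level: float
    background_level: float


def gen_wing_image(
    n_wings: int,
    canvas_px: tuple[int, int] = (1000, 1000),
    Sb: float = 0.04,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    wing_level: float = 0.2,
    background_level: float = 1.0,
    axis_frac: tuple[float, float] = (0.06, 0.13),
    max_tries: int = 200,
) -> SyntheticWingImage:
    """Render non-overlapping elliptical wing silhouettes on white.

    Silhouettes are ellipse unions — only the pixel-count truth matters
    for the area formula, not realistic outlines.  ``noise_sd`` is the
    additive Gaussian noise level as a fraction of the wing/background
    contrast.  Raises if the requested wings cannot be placed without
    overlap within a bounded number of retries.
    """
    from skimage.draw import ellipse as draw_ellipse

    rows, cols = canvas_px
    if rows <= 0 or cols <= 0:
        raise ValueError("canvas must be non-empty")
    rng = np.random.default_rng(seed)
    mask = np.zeros((rows, cols), dtype=bool)
    short = min(rows, cols)

    for w in range(n_wings):
        for attempt in range(max_tries):
            a = rng.uniform(*axis_frac) * short
            b = rng.uniform(*axis_frac) * short
            rot = rng.uniform(0, np.pi)
            margin = max(a, b) + 2
            r0 = rng.uniform(margin, rows - margin)
            c0 = rng.uniform(margin, cols - margin)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(rows, cols), rotation=rot)
            if not mask[rr, cc].any():
                mask[rr, cc] = True
                break
        else:
            raise RuntimeError(
                f"could not place wing {w + 1}/{n_wings} without overlap "
                f"after {max_tries} tries"
            )

    image = np.full((rows, cols), background_level, dtype=np.float64)
    image[mask] = wing_level
    if noise_sd > 0:
        contrast = background_level - wing_level
        image = image + rng.normal(0.0, noise_sd * contrast, size=image.shape)
        image = np.clip(image, 0.0, 1.0)
    return SyntheticWingImage(
        image=image,
        mask=mask,
        n_wing_px=int(mask.sum()),
        wing_level=wing_level,
        background_level=background_level,
    )


# ---------------------------------------------------------------------------
# Repeated-measures tables

#: Default per-group mean absorption-factor curves over the 8 bands
#: 20-100 kHz, shaped like the measured spectra: every group peaks at
#: 20-25 kHz; chalcosiines peak near 0.4, saturniids near 0.6, with the
#: male saturniids declining most steeply towards high frequency.
DEFAULT_GROUP_CURVES = {
    "chalcosiine": [0.38, 0.40, 0.36, 0.30, 0.26, 0.24, 0.22, 0.20],
    "female-saturniid": [0.58, 0.62, 0.55, 0.46, 0.38, 0.33, 0.30, 0.28],
    "male-saturniid": [0.55, 0.60, 0.45, 0.32, 0.25, 0.21, 0.18, 0.16],
}

DEFAULT_BANDS_HZ = [20_000.0, 25_000.0, 31_500.0, 40_000.0,
                    50_000.0, 63_000.0, 80_000.0, 100_000.0]

#: The study's nine preparations: three chalcosiine species (males only)
#: and both sexes of three saturniid species.
DEFAULT_PREPARATIONS = {
    "A_a_analis": "chalcosiine",
    "C_burmanus": "chalcosiine",
    "E_pulchera": "chalcosiine",
    "A_io_F": "female-saturniid",
    "A_mittrei_F": "female-saturniid",
    "S_c_ricini_F": "female-saturniid",
    "A_io_M": "male-saturniid",
    "A_mittrei_M": "male-saturniid",
    "S_c_ricini_M": "male-saturniid",
}


def default_rm_means(prep_offset: float = 0.02) -> pd.DataFrame:
    """Long table of mean alpha per (preparation, band).

    Preparations within a group share the group curve plus a small fixed
    offset (-prep_offset, 0, +prep_offset) so preparations are
    distinguishable but group structure dominates.
    """
    rows = []
    group_counter: dict[str, int] = {}
    for prep, group in DEFAULT_PREPARATIONS.items():
        i = group_counter.get(group, 0)
        group_counter[group] = i + 1
        offset = (i - 1) * prep_offset
        for fc, mean in zip(DEFAULT_BANDS_HZ, DEFAULT_GROUP_CURVES[group]):
            rows.append(
                {"preparation": prep, "group": group, "fc_hz": fc,
                 "mean_alpha": mean + offset}
            )
    return pd.DataFrame(rows)


def gen_rm_dataset(
    group_band_means: pd.DataFrame | None = None,
    sd: float = 0.05,
    n_sets: int = 6,
    seed: int = 0,
    *,
    subject_sd: float = 0.03,
) -> RMDataset:
    """Balanced long-format absorption table with subject random effects.

    ``alpha = mean(preparation, band) + b_subject + eps`` with
    ``b ~ N(0, subject_sd^2)`` shared across a subject's bands and
    ``eps ~ N(0, sd^2)`` independent per record.  With the default
    9-preparation design, 6 sets and 8 bands the table has
    9 x 6 x 8 = 432 records.
    """
    if sd <= 0:
        raise ValueError("residual sd must be positive")
    if subject_sd < 0:
        raise ValueError("subject sd must be nonnegative")
    if group_band_means is None:
        group_band_means = default_rm_means()
    required = {"preparation", "group", "fc_hz", "mean_alpha"}
    if not required.issubset(group_band_means.columns):
        raise ValueError(f"means table needs columns {sorted(required)}")

    rng = np.random.default_rng(seed)
    rows = []
    for prep, sub in group_band_means.groupby("preparation", sort=True):
        group = sub["group"].iloc[0]
        sub = sub.sort_values("fc_hz")
        for s in range(n_sets):
            b = rng.normal(0.0, subject_sd)
            eps = rng.normal(0.0, sd, size=len(sub))
            for (fc, mean), e in zip(sub[["fc_hz", "mean_alpha"]].values, eps):
                rows.append(
                    {"preparation": prep, "group": group,
                     "set_id": f"{prep}_set{s}", "fc_hz": fc,
                     "alpha": mean + b + e}
                )
    return RMDataset(pd.DataFrame(rows))
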