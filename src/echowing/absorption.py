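"""Random-incidence absorption factors from reverberation times.

The reverberation-chamber method compares the Sabine decay of the empty
chamber (reverberation time ``T0``) with the decay after an absorbent
sample is introduced (``T1``).  With spatially averaged reverberation
times and an air-attenuation correction, the empty-chamber absorption
factor is

    alpha_0 = 55.25 V / (c S T0) - 4 m1 V / S

and the sample (wing-set) absorption factor follows from the difference
of the two measurements,

    alpha_w = 55.25 V / (c S_w) * (1/T1 - 1/T0),

where ``V`` and ``S`` are the chamber volume and surface area, ``S_w``
the sample planform area, ``c`` the speed of sound and ``m1`` the air
volume absorption coefficient (the classical thermoviscous law averaged
over the analysis band).  Air terms cancel in the difference form
because both measurements share the same air conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AirProperties, Band, ChamberSpec, ReverbMeasurement, WingSetGeometry

#: Sabine constant: 24 * ln(10) rounded as conventionally printed.
SABINE_CONST = 55.25

#: ANSI/IEC preferred 1/3-octave centre frequencies for one decade,
#: scaled by powers of ten to cover any range.
_PREFERRED_CENTRES_DECADE = np.array(
    [1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0]
)


def third_octave_bands(
    fc_lo: float, fc_hi: float, convention: str = "base-2"
) -> list[Band]:
    """Preferred-centre 1/3-octave bands covering [fc_lo, fc_hi] inclusive.

    Centres follow the preferred-number series (..., 20, 25, 31.5, 40,
    50, 63, 80, 100 kHz, ...); edges are ``fc / G**(1/6)`` and
    ``fc * G**(1/6)`` with ``G = 2`` or ``10**0.3``.
    """
    if fc_lo > fc_hi:
        raise ValueError("fc_lo must not exceed fc_hi")
    decades = np.arange(
        np.floor(np.log10(fc_lo)) - 1, np.ceil(np.log10(fc_hi)) + 1
    )
    centres = np.sort(
        np.concatenate([_PREFERRED_CENTRES_DECADE * 10.0**d for d in decades])
    )
    sel = centres[(centres >= fc_lo * (1 - 1e-9)) & (centres <= fc_hi * (1 + 1e-9))]
    return [Band.from_centre(fc, convention) for fc in sel]


def default_band_set(nine: bool = False, convention: str = "base-2") -> list[Band]:
    """The ultrasonic analysis bands, 20-100 kHz.

    The default is the 8 preferred centres {20, 25, 31.5, 40, 50, 63,
    80, 100} kHz.  ``nine=True`` additionally includes 16 kHz so that
    nine consecutive 1/3-octave bands end at 100 kHz, for workflows that
    count nine bands.
    """
    lo = 16_000.0 if nine else 20_000.0
    return third_octave_bands(lo, 100_000.0, convention)


@dataclass(frozen=True)
class AirAbsorptionResult:
    """Band-averaged classical air volume absorption coefficient (1/m)."""

    band: Band
    m1: float


def classical_air_attenuation(f: np.ndarray | float, air: AirProperties) -> np.ndarray:
    """Classical (Stokes-Kirchhoff) energy attenuation coefficient in 1/m.

    Thermoviscous dissipation only — molecular relaxation is deliberately
    excluded, as appropriate for the small path lengths inside a bench-top
    chamber:

        m(f) = (4 pi^2 f^2 / (rho c^3)) * [ (4/3) mu + (gamma - 1) k / Cp ]
    """
    f = np.asarray(f, dtype=np.float64)
    coeff = (4.0 / 3.0) * air.mu + (air.gamma - 1.0) * air.k_th / air.Cp
    return 4.0 * np.pi**2 * f**2 * coeff / (air.rho * air.c**3)


def air_attenuation_band(band: Band, air: AirProperties) -> AirAbsorptionResult:
    """Average the classical attenuation coefficient over the band.

    The f^2 law integrates in closed form:

        m1 = C * (fh^3 - fl^3) / (3 (fh - fl)),

    with ``C = 4 pi^2 [(4/3) mu + (gamma-1) k/Cp] / (rho c^3)``.  In the
    degenerate limit ``fh -> fl`` this reduces to the single-frequency
    coefficient at fl.
    """
    fl, fh = band.fl, band.fh
    coeff = (4.0 / 3.0) * air.mu + (air.gamma - 1.0) * air.k_th / air.Cp
    C = 4.0 * np.pi**2 * coeff / (air.rho * air.c**3)
    if np.isclose(fh, fl, rtol=1e-12):
        m1 = C * fl**2
    else:
        m1 = C * (fh**3 - fl**3) / (3.0 * (fh - fl))
    return AirAbsorptionResult(band=band, m1=float(m1))


def empty_chamber_alpha(
    chamber: ChamberSpec,
    band: Band,
    T0: ReverbMeasurement,
    air: AirProperties,
) -> float:
    """Absorption factor of the empty chamber from its reverberation time."""
    if T0.t60 <= 0:
        raise ValueError("reverberation time must be positive")
    m1 = air_attenuation_band(band, air).m1
    sabine = SABINE_CONST * chamber.V / (air.c * chamber.S * T0.t60)
    return float(sabine - 4.0 * m1 * chamber.V / chamber.S)


def wing_alpha(
    chamber: ChamberSpec,
    band: Band,
    T0: ReverbMeasurement,
    T1: ReverbMeasurement,
    geom: WingSetGeometry,
    air: AirProperties,
) -> float:
    """Absorption factor of an introduced wing set.

    Difference form: the air-attenuation term is identical before and
    after the sample is introduced and cancels, so only the change in
    1/T matters.  ``T1 = T0`` therefore gives exactly zero.
    """
    if T0.t60 <= 0 or T1.t60 <= 0:
        raise ValueError("reverberation times must be positive")
    if geom.Sw <= 0:
        raise ValueError("wing planform area must be positive")
    return float(
        SABINE_CONST
        * chamber.V
        / (air.c * geom.Sw)
        * (1.0 / T1.t60 - 1.0 / T0.t60)
    )


def invert_empty_chamber_alpha(
    chamber: ChamberSpec, band: Band, alpha0: float, air: AirProperties
) -> float:
    """Reverberation time T0 that produces a given empty-chamber alpha."""
    m1 = air_attenuation_band(band, air).m1
    denom = air.c * (chamber.S * alpha0 + 4.0 * m1 * chamber.V)
    if denom <= 0:
        raise ValueError("alpha0 too small: inverted T0 not positive/finite")
    return float(SABINE_CONST * chamber.V / denom)


def invert_wing_alpha(
    chamber: ChamberSpec,
    band: Band,
    alpha0: float,
    alphaw: float,
    Sw: float,
    air: AirProperties,
) -> tuple[float, float]:
    """(T0, T1) pair that realises the given empty and wing-set alphas."""
    T0 = invert_empty_chamber_alpha(chamber, band, alpha0, air)
    inv_T1 = 1.0 / T0 + alphaw * air.c * Sw / (SABINE_CONST * chamber.V)
    if inv_T1 <= 0:
        raise ValueError("alphaw too large: inverted T1 not positive")
    return T0, float(1.0 / inv_T1)
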