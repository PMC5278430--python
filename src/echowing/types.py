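"""Shared domain types for the ultrasonic absorption pipeline.

All quantities are SI (seconds, Hz, metres); decibel levels are
``10*log10`` of energy-like quantities. Absorption factors are reported
raw, without clamping to [0, 1]: diffuse-field measurements routinely
stray outside the physical range through noise, and clamping would bias
any spatial or per-set average. A warning is logged instead.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("echowing")

#: fh/fl for a 1/3-octave band, base-2 convention.
THIRD_OCTAVE_RATIO_BASE2 = 2.0 ** (1.0 / 3.0)
#: fh/fl for a 1/3-octave band, base-10 convention (ANSI S1.11 exact).
THIRD_OCTAVE_RATIO_BASE10 = 10.0 ** (3.0 / 10.0)


@dataclass(frozen=True)
class Band:
    """One 1/3-octave analysis band.

    Parameters
    ----------
    fc : float
        Centre frequency in Hz.
    fl, fh : float
        Lower and upper band-edge frequencies in Hz.  ``fh/fl`` must equal
        the third-octave ratio of either the base-2 or base-10 convention.
    """

    fc: float
    fl: float
    fh: float

    def __post_init__(self) -> None:
        if not (0 < self.fl < self.fc < self.fh):
            raise ValueError(
                f"band edges must satisfy 0 < fl < fc < fh, got "
                f"fl={self.fl}, fc={self.fc}, fh={self.fh}"
            )
        ratio = self.fh / self.fl
        if not (
            np.isclose(ratio, THIRD_OCTAVE_RATIO_BASE2, rtol=1e-6)
            or np.isclose(ratio, THIRD_OCTAVE_RATIO_BASE10, rtol=1e-6)
        ):
            raise ValueError(
                f"fh/fl = {ratio:.8f} is not a third-octave ratio "
                f"(expected {THIRD_OCTAVE_RATIO_BASE2:.8f} or "
                f"{THIRD_OCTAVE_RATIO_BASE10:.8f})"
            )

    @classmethod
    def from_centre(cls, fc: float, convention: str = "base-2") -> "Band":
        """Build the band around a centre frequency.

        ``fl = fc / G**(1/6)`` and ``fh = fc * G**(1/6)`` with ``G = 2``
        (base-2) or ``G = 10**0.3`` (base-10).
        """
        if convention == "base-2":
            half = 2.0 ** (1.0 / 6.0)
        elif convention == "base-10":
            half = 10.0 ** (3.0 / 20.0)
        else:
            raise ValueError(f"unknown convention {convention!r}")
        return cls(fc=float(fc), fl=fc / half, fh=fc * half)


@dataclass
class Recording:
    """A mono pressure recording with sound-offset metadata.

    ``samples`` are in arbitrary linear units; ``tau_off`` is the time at
    which the excitation stopped (start of free decay), in seconds from
    the start of the recording.
    """

    samples: np.ndarray
    fs: float
    tau_off: float
    position_id: str = "pos0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not (0 <= self.tau_off < self.duration):
            raise ValueError(
                f"tau_off={self.tau_off} outside [0, {self.duration}) s"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def to_wav(self, path: str | Path, truth: dict | None = None) -> None:
        """Write float32 WAV plus a JSON sidecar with the metadata."""
        from scipy.io import wavfile

        path = Path(path)
        wavfile.write(path, int(round(self.fs)), self.samples.astype(np.float32))
        sidecar = {
            "fs": self.fs,
            "tau_off": self.tau_off,
            "position_id": self.position_id,
        }
        if truth is not None:
            sidecar["truth"] = truth
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_wav(cls, path: str | Path) -> "Recording":
        from scipy.io import wavfile

        path = Path(path)
        fs, samples = wavfile.read(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            samples=np.asarray(samples, dtype=np.float64),
            fs=float(meta.get("fs", fs)),
            tau_off=float(meta.get("tau_off", 0.0)),
            position_id=str(meta.get("position_id", path.stem)),
        )


@dataclass
class EnvelopeCurve:
    """Nonnegative signal envelope on a uniform time grid."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("empty envelope")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class SchroederCurve:
    """Backward-integrated decay curve in dB re the level at sound offset.

    ``level_db`` is 0 dB at ``times[0]`` (the sound offset) and
    non-increasing; ``slope_A`` (dB/s) and ``intercept_B`` (dB) describe
    the least-squares line fitted over the evaluation range, with the
    time origin at the offset.
    """

    level_db: np.ndarray
    times: np.ndarray
    tau_N: float
    slope_A: float | None = None
    intercept_B: float | None = None

    def __post_init__(self) -> None:
        self.level_db = np.asarray(self.level_db, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.level_db.shape != self.times.shape:
            raise ValueError("level_db and times must have the same shape")


@dataclass(frozen=True)
class ChamberSpec:
    """Reverberation-chamber geometry: volume V (m^3), surface area S (m^2)."""

    V: float
    S: float

    def __post_init__(self) -> None:
        if self.V <= 0 or self.S <= 0:
            raise ValueError("chamber volume and surface must be positive")


@dataclass(frozen=True)
class AirProperties:
    """Thermophysical properties of humid air.

    Defaults are standard values at 20 degC and atmospheric pressure.

    Attributes
    ----------
    c : speed of sound (m/s)
    mu : dynamic viscosity (Pa s)
    rho : density (kg/m^3)
    gamma : ratio of specific heats
    Pr : Prandtl number
    Cp : isobaric heat capacity (J/(kg K))
    k_th : thermal conductivity (W/(m K))
    temp_C : temperature (degC)
    rh : relative humidity (%)
    """

    c: float = 343.2
    mu: float = 1.814e-5
    rho: float = 1.204
    gamma: float = 1.400
    Pr: float = 0.713
    Cp: float = 1005.0
    k_th: float = 2.514e-2
    temp_C: float = 20.0
    rh: float = 70.0

    def __post_init__(self) -> None:
        for name in ("c", "mu", "rho", "Pr", "Cp", "k_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"air property {name} must be positive")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")


@dataclass(frozen=True)
class ReverbMeasurement:
    """Spatially averaged reverberation time for one band."""

    band: Band
    t60: float
    n_positions: int = 1

    def __post_init__(self) -> None:
        if self.t60 <= 0:
            raise ValueError("reverberation time must be positive")
        if self.n_positions < 1:
            raise ValueError("need at least one microphone position")


@dataclass
class AbsorptionSpectrum:
    """Per-band absorption factors for one subject (chamber or wing set)."""

    entries: list[tuple[Band, float]]
    subject_id: str
    kind: str = "wing-set"  # "empty-chamber" | "wing-set"

    def __post_init__(self) -> None:
        if self.kind not in ("empty-chamber", "wing-set"):
            raise ValueError(f"unknown kind {self.kind!r}")
        alphas = np.array([a for _, a in self.entries], dtype=np.float64)
        if not np.all(np.isfinite(alphas)):
            raise ValueError("absorption factors must be finite")
        out_of_range = (alphas < 0) | (alphas > 1)
        if np.any(out_of_range):
            logger.warning(
                "%s/%s: %d absorption factor(s) outside [0, 1] kept raw",
                self.subject_id, self.kind, int(out_of_range.sum()),
            )

    @property
    def bands(self) -> list[Band]:
        return [b for b, _ in self.entries]

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for _, a in self.entries], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "kind": self.kind,
                "fc_hz": [b.fc for b, _ in self.entries],
                "alpha": [a for _, a in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, convention: str = "base-2") -> "AbsorptionSpectrum":
        df = pd.read_csv(path)
        return cls.from_frame(df, convention=convention)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, convention: str = "base-2") -> "AbsorptionSpectrum":
        subject = str(df["subject_id"].iloc[0]) if "subject_id" in df else "subject"
        kind = str(df["kind"].iloc[0]) if "kind" in df else "wing-set"
        entries = [
            (Band.from_centre(fc, convention), float(a))
            for fc, a in zip(df["fc_hz"], df["alpha"])
        ]
        return cls(entries=entries, subject_id=subject, kind=kind)


@dataclass(frozen=True)
class WingSetGeometry:
    """Pixel counts and areas entering the planform-area estimate."""

    Sw: float
    Sb: float
    Nw: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.Nw <= self.N):
            raise ValueError("wing pixel count must lie in [0, N]")
        if not (0 <= self.Sw <= self.Sb):
            raise ValueError("wing area must lie in [0, Sb]")


@dataclass(frozen=True)
class SonarScenario:
    """Paired detection-distance comparison of two targets.

    The two targets are assumed identical in size, shape, source level,
    detection threshold and noise; they differ only in wing absorption
    (``alpha1`` for the target of interest, ``alpha2`` for the
    reference), so those common sonar-equation terms cancel and never
    enter numerically.
    """

    r2: float
    lam: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.r2 <= 0:
            raise ValueError("reference distance must be positive")
        if self.lam < 0:
            raise ValueError("atmospheric attenuation must be nonnegative")
        for a in (self.alpha1, self.alpha2):
            if not (0 <= a < 1):
                raise ValueError(
                    f"absorption factor {a} outside [0, 1); total absorption "
                    "leaves no echo to model"
                )


RM_COLUMNS = ["preparation", "group", "set_id", "fc_hz", "alpha"]
RM_GROUPS = ("chalcosiine", "female-saturniid", "male-saturniid")


@dataclass
class RMDataset:
    """Long-format absorption table for the repeated-measures analysis.

    One record per (preparation, set, band): ``preparation`` is the
    between-subjects label, each (preparation, set_id) pair is one
    subject, and the band centre frequency is the within-subject factor.
    The design must be balanced: every subject has exactly one record per
    band.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.data = self.data[RM_COLUMNS].copy()
        counts = self.data.groupby(["preparation", "set_id"])["fc_hz"].agg(
            ["count", "nunique"]
        )
        bad = counts[counts["count"] != counts["nunique"]]
        if len(bad):
            raise ValueError(
                f"duplicate band records for subject(s) {list(bad.index)[:3]}"
            )
        n_bands = counts["count"].unique()
        if len(n_bands) != 1:
            raise ValueError(
                "unbalanced design: subjects have differing band counts "
                f"{sorted(n_bands)}"
            )

    @property
    def preparations(self) -> list[str]:
        return sorted(self.data["preparation"].unique())

    @property
    def bands_hz(self) -> np.ndarray:
        return np.sort(self.data["fc_hz"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RMDataset":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Configuration I/O

def load_config(path: str | Path) -> tuple[ChamberSpec, AirProperties]:
    """Read chamber geometry and air properties from a YAML/JSON file.

    Expected layout::

        chamber: {V: 0.008, S: 0.28}
        air: {c: 343.2, mu: 1.814e-5, ...}   # missing keys use defaults
    """
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text)
    if "chamber" not in cfg:
        raise ValueError(f"config {path} lacks a 'chamber' section")
    chamber = ChamberSpec(**{k: float(v) for k, v in cfg["chamber"].items()})
    air = AirProperties(**{k: float(v) for k, v in cfg.get("air", {}).items()})
    return chamber, air


def save_config(chamber: ChamberSpec, air: AirProperties, path: str | Path) -> None:
    cfg = {
        "chamber": {"V": chamber.V, "S": chamber.S},
        "air": {
            "c": air.c, "mu": air.mu, "rho": air.rho, "gamma": air.gamma,
            "Pr": air.Pr, "Cp": air.Cp, "k_th": air.k_th,
            "temp_C": air.temp_C, "rh": air.rh,
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
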