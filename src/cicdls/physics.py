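"""Single-angle DLS physics: instrument geometry, Stokes-Einstein diffusion,
and exponential decay rates.

The quantities here connect a hydrodynamic radius ``R_h`` (nm) to the decay
rate of the field autocorrelation function measured at one scattering angle:

    q     = (4 pi n / lambda_0) * sin(theta / 2)        scattering vector
    D     = k_B T / (6 pi eta R_h)                      Stokes-Einstein
    Gamma = D * q**2                                    decay rate of g1

All radii are hydrodynamic radii in nanometres throughout the package; no
diameters appear anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_K",
    "InstrumentConfig",
    "scattering_vector",
    "diffusion_coefficient",
    "decay_rate",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_K = 1.380649e-23

#: Correlator bands (Hz) accepted without a warning.
_STANDARD_BANDS = (2048, 8096)


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and thermodynamic parameters of a single-angle DLS instrument.

    Defaults describe a standard He-Ne setup measuring a dilute aqueous
    sample at 25 C: 632.8 nm vacuum wavelength, 90 degree detection, water
    refractive index and viscosity.

    Parameters
    ----------
    wavelength_nm : float
        Laser wavelength in vacuum, lambda_0 (nm).
    scattering_angle_deg : float
        Detection angle theta, in (0, 180) degrees.
    refractive_index : float
        Solvent refractive index n (>= 1).
    temperature_K : float
        Absolute temperature T (K).
    viscosity_Pa_s : float
        Solvent dynamic viscosity eta (Pa s).
    sampling_band_Hz : float
        Correlator sampling band.  2048 and 8096 Hz are the conventional
        settings; other positive values are accepted with a warning.
    n_channels : int
        Number of lag channels of the simulated correlator.
    acquisition_s : float
        Nominal acquisition time per sample (metadata only).
    """

    wavelength_nm: float = 632.8
    scattering_angle_deg: float = 90.0
    refractive_index: float = 1.333
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.00089
    sampling_band_Hz: float = 2048
    n_channels: int = 256
    acquisition_s: float = 900.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if not 0 < self.scattering_angle_deg < 180:
            raise ValueError("scattering_angle_deg must lie in (0, 180)")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if self.viscosity_Pa_s <= 0:
            raise ValueError("viscosity_Pa_s must be positive")
        if self.sampling_band_Hz <= 0:
            raise ValueError("sampling_band_Hz must be positive")
        if self.sampling_band_Hz not in _STANDARD_BANDS:
            warnings.warn(
                f"non-standard correlator band {self.sampling_band_Hz} Hz "
                f"(conventional settings: {_STANDARD_BANDS})",
                stacklevel=3,
            )
        if self.n_channels < 8:
            raise ValueError("n_channels must be >= 8")

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "scattering_angle_deg": self.scattering_angle_deg,
            "refractive_index": self.refractive_index,
            "temperature_K": self.temperature_K,
            "viscosity_Pa_s": self.viscosity_Pa_s,
            "sampling_band_Hz": self.sampling_band_Hz,
            "n_channels": self.n_channels,
            "acquisition_s": self.acquisition_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def scattering_vector(config: InstrumentConfig) -> float:
    """Magnitude of the scattering vector q in 1/m.

    q = (4 pi n / lambda_0) * sin(theta / 2), with lambda_0 in metres.
    """
    lam_m = config.wavelength_nm * 1e-9
    theta = math.radians(config.scattering_angle_deg)
    return 4.0 * math.pi * config.refractive_index / lam_m * math.sin(theta / 2.0)


def diffusion_coefficient(radius_nm: float, config: InstrumentConfig) -> float:
    """Stokes-Einstein translational diffusion coefficient, m^2/s."""
    radius_nm = float(radius_nm)
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    r_m = radius_nm * 1e-9
    return BOLTZMANN_K * config.temperature_K / (
        6.0 * math.pi * config.viscosity_Pa_s * r_m
    )


def decay_rate(radius_nm, config: InstrumentConfig):
    """Field-correlation decay rate Gamma = D q^2 in 1/s.

    Accepts a scalar radius or an array of radii (nm).
    """
    radius = np.asarray(radius_nm, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("radius_nm must be positive")
    q = scattering_vector(config)
    d = BOLTZMANN_K * config.temperature_K / (
        6.0 * math.pi * config.viscosity_Pa_s * (radius * 1e-9)
    )
    gamma = d * q * q
    return float(gamma) if np.isscalar(radius_nm) else gamma
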