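"""Electron kinematics and the annular probe profile.

The probe is a ring-shaped (annular) beam of internal radius r0 and
waist dr that passes around the molecule without hitting it (aloof
geometry) and couples to electronic transitions through its Coulomb
field.  The reference transverse amplitude is a Gaussian annulus

    a(r) = N * exp(-(r - r0)^2 / dr^2),

normalized so that the two-dimensional probability integral
int_0^inf |a(r)|^2 2 pi r dr equals one.  Alternative radial profiles
can be registered without touching downstream code.

Kinematics are relativistic: for swift electrons (30-300 keV) the
velocity and wavenumber follow from gamma = 1 + T/(m c^2).  The maximum
collected transverse wavenumber is the small-angle cutoff
k_max = alpha * k_parallel with alpha the collection semi-angle in rad.
Longitudinal momentum transfer uses the non-recoil value p = -omega/v,
standard when the loss omega is tiny compared with the beam energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, special

from .units import C_AU, ev_to_hartree

__all__ = [
    "BeamParameters",
    "Kinematics",
    "compute_kinematics",
    "annular_amplitude",
    "profile_normalization",
    "longitudinal_momentum",
    "RADIAL_PROFILES",
]

#: registry of radial profile shapes: name -> shape(r, r0, dr)
RADIAL_PROFILES: dict[str, Callable] = {
    "gaussian_annulus": lambda r, r0, dr: np.exp(-((r - r0) / dr) ** 2),
}


@dataclass(frozen=True)
class BeamParameters:
    """Annular probe geometry, kinetic energy and the OAM window.

    Defaults are the reference configuration of the simulations: 60 keV
    beam, 200 mrad collection semi-angle, annulus radius 7 bohr with a
    3 bohr waist, OAM channels l in [-3, 3].
    """

    kinetic_energy_kev: float = 60.0
    r0: float = 7.0
    dr: float = 3.0
    alpha_mrad: float = 200.0
    l_range: tuple[int, int] = (-3, 3)
    axis_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    profile: str = "gaussian_annulus"

    def __post_init__(self):
        if self.kinetic_energy_kev <= 0:
            raise ValueError("kinetic energy must be positive")
        if self.r0 <= 0 or self.dr <= 0 or self.alpha_mrad <= 0:
            raise ValueError("r0, dr and alpha must be positive")
        lo, hi = self.l_range
        if lo != -hi:
            raise ValueError("l_range must be symmetric about 0")
        if self.profile not in RADIAL_PROFILES:
            raise ValueError(f"unknown radial profile {self.profile!r}")

    @property
    def l_values(self) -> list[int]:
        lo, hi = self.l_range
        return list(range(lo, hi + 1))

    @property
    def m_max(self) -> int:
        return max(abs(l) for l in self.l_range)


@dataclass(frozen=True)
class Kinematics:
    """Derived relativistic quantities, all in atomic units."""

    gamma: float
    velocity: float
    k_parallel: float
    wavelength: float
    k_max: float

    def __post_init__(self):
        if not (0 < self.velocity < C_AU):
            raise ValueError("velocity must satisfy 0 < v < c")
        if self.k_max <= 0:
            raise ValueError("k_max must be positive")


def compute_kinematics(beam: BeamParameters) -> Kinematics:
    """Relativistic velocity, wavenumber and collection cutoff.

    gamma = 1 + T / (m c^2); v = c sqrt(1 - gamma^-2); the incident
    wavenumber equals the relativistic momentum gamma*v (a.u.), and
    k_max = alpha * k_parallel for a collection semi-angle alpha (rad).
    """
    t_ha = ev_to_hartree(beam.kinetic_energy_kev * 1e3)
    gamma = 1.0 + t_ha / C_AU**2
    velocity = C_AU * math.sqrt(1.0 - gamma**-2)
    k_parallel = gamma * velocity
    return Kinematics(
        gamma=gamma,
        velocity=velocity,
        k_parallel=k_parallel,
        wavelength=2.0 * math.pi / k_parallel,
        k_max=beam.alpha_mrad * 1e-3 * k_parallel,
    )


def profile_normalization(beam: BeamParameters) -> float:
    """Normalization constant N with int |a|^2 2 pi r dr = 1.

    For the Gaussian annulus the weighted norm has the closed form

        I = int_0^inf exp(-2 (r-r0)^2/dr^2) r dr
          = (dr^2/4) exp(-2 r0^2/dr^2)
            + r0 (dr/2) sqrt(pi/2) (1 + erf(sqrt(2) r0/dr));

    other registered profiles fall back to adaptive quadrature.
    """
    r0, dr = beam.r0, beam.dr
    if beam.profile == "gaussian_annulus":
        i_r = (dr**2 / 4.0) * math.exp(-2.0 * (r0 / dr) ** 2) + r0 * (
            dr / 2.0
        ) * math.sqrt(math.pi / 2.0) * (1.0 + special.erf(math.sqrt(2.0) * r0 / dr))
    else:
        shape = RADIAL_PROFILES[beam.profile]
        i_r, _ = integrate.quad(
            lambda r: shape(r, r0, dr) ** 2 * r, 0.0, r0 + 12.0 * dr
        )
    return 1.0 / math.sqrt(2.0 * math.pi * i_r)


def annular_amplitude(r, beam: BeamParameters):
    """Transverse amplitude a(r) of the incident annular beam (bohr^-1)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    shape = RADIAL_PROFILES[beam.profile]
    return profile_normalization(beam) * shape(r, beam.r0, beam.dr)


def longitudinal_momentum(omega_ev: float, kin: Kinematics) -> float:
    """Non-recoil longitudinal momentum transfer p = k_fz - k_iz = -omega/v.

    The scattered electron's longitudinal wavenumber is reduced by the
    loss; the energy-conserving sum over final k_fz collapses onto this
    single value for swift electrons.
    """
    if omega_ev <= 0:
        raise ValueError("energy loss must be positive")
    return -ev_to_hartree(omega_ev) / kin.velocity
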