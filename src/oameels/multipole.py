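"""Cylindrical multipole decomposition of transition potentials.

The loss rate per OAM channel depends on the transition potential only
through its transverse component, i.e. the Fourier transform of
V_0n(x, y, z) along the beam axis at the longitudinal momentum transfer
p, expanded in azimuthal harmonics about the axis:

    Vt(r, phi; p) = sum_m Vt^(m)(r; p) exp(+i m phi),
    Vt^(m)(r; p)  = (1/2 pi) int Vt(r, phi; p) exp(-i m phi) dphi.

m = 0 is the monopole, m = +-1 the dipole, m = +-2 the quadrupole.  The
analysis kernel exp(-i m phi) together with the final-state azimuthal
factor exp(-i l phi) fixes the selection rule l = -m (see
:mod:`oameels.rates`).  The expansion proceeds in three steps, each its
own operation so it can be validated independently: a trapezoid z
transform, a Cartesian-to-polar resampling, and a discrete azimuthal
Fourier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import AliasingError, OutOfExtentError
from .volumetric import VolumetricGrid

__all__ = [
    "TransverseField",
    "PolarField",
    "MultipoleComponents",
    "longitudinal_ft",
    "resample_polar",
    "azimuthal_decompose",
    "reconstruct_polar",
]


@dataclass
class TransverseField:
    """z-Fourier-transformed potential on the parent (x, y) lattice."""

    p: float
    values: np.ndarray          # complex, shape (nx, ny)
    x: np.ndarray
    y: np.ndarray
    axis_center: np.ndarray     # (cx, cy) in grid coordinates

    def __post_init__(self):
        self.axis_center = np.asarray(self.axis_center, dtype=float).reshape(2)
        if self.values.shape != (len(self.x), len(self.y)):
            raise ValueError("field shape does not match the (x, y) lattice")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("transverse field must be finite")

    def inscribed_radius(self) -> float:
        cx, cy = self.axis_center
        return float(
            min(cx - self.x[0], self.x[-1] - cx, cy - self.y[0], self.y[-1] - cy)
        )


@dataclass
class PolarField:
    """Complex field on a uniform polar lattice about the beam axis.

    The radial lattice starts at half a step (the r dr measure makes the
    axis point irrelevant, and the field value exactly on the axis is
    ambiguous to interpolate).
    """

    radii: np.ndarray           # (n_r,), strictly increasing
    phis: np.ndarray            # (n_phi,), 2 pi k / n_phi
    values: np.ndarray          # complex, (n_r, n_phi)
    p: float = 0.0

    def __post_init__(self):
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.values.shape != (len(self.radii), len(self.phis)):
            raise ValueError("polar values shape mismatch")

    @property
    def n_phi(self) -> int:
        return len(self.phis)


@dataclass
class MultipoleComponents:
    """Complex radial profiles Vt^(m)(r; p) for m in [-m_max, m_max]."""

    p: float
    m_max: int
    radii: np.ndarray
    coeffs: np.ndarray          # complex, (2 m_max + 1, n_r), row 0 is m = -m_max

    def __post_init__(self):
        if self.coeffs.shape != (2 * self.m_max + 1, len(self.radii)):
            raise ValueError("component count must be 2 m_max + 1")
        if not np.all(np.isfinite(self.coeffs.view(float))):
            raise ValueError("multipole profiles must be finite")

    def component(self, m: int) -> np.ndarray:
        if abs(m) > self.m_max:
            raise ValueError(f"|m| = {abs(m)} exceeds m_max = {self.m_max}")
        return self.coeffs[m + self.m_max]


def longitudinal_ft(grid: VolumetricGrid, p: float, axis_center=(0.0, 0.0)) -> TransverseField:
    """Trapezoid Fourier transform along z:  sum_z V exp(-i p z) dz.

    At p = 0 this reduces exactly to :func:`oameels.volumetric.project_z`.
    """
    grid.require_orthogonal()
    z = grid.z_coords
    integrand = grid.values * np.exp(-1j * p * z)
    values = np.trapezoid(integrand, x=z, axis=2)
    return TransverseField(
        p=p, values=values, x=grid.x_coords, y=grid.y_coords,
        axis_center=np.asarray(axis_center, dtype=float),
    )


def resample_polar(
    field: TransverseField,
    n_r: int,
    r_max: float,
    n_phi: int,
    method: str = "cubic",
) -> PolarField:
    """Interpolate the transverse field onto a uniform polar lattice.

    ``method`` is any :class:`RegularGridInterpolator` method; the
    default cubic spline keeps interpolation-induced azimuthal aliasing
    far below the OAM selection-rule floor, while "linear" (bilinear)
    remains available.  Requests beyond the grid's inscribed transverse
    radius raise rather than extrapolate.
    """
    inscribed = field.inscribed_radius()
    if r_max > inscribed * (1.0 + 1e-12):
        raise OutOfExtentError(
            f"r_max = {r_max:g} bohr exceeds the inscribed transverse radius "
            f"{inscribed:g} bohr of the grid"
        )
    dr = r_max / n_r
    radii = (np.arange(n_r) + 0.5) * dr
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    cx, cy = field.axis_center
    pts = np.empty((n_r, n_phi, 2))
    pts[..., 0] = cx + radii[:, None] * np.cos(phis)[None, :]
    pts[..., 1] = cy + radii[:, None] * np.sin(phis)[None, :]
    interp_re = RegularGridInterpolator((field.x, field.y), field.values.real, method=method)
    vals = interp_re(pts).astype(complex)
    if np.iscomplexobj(field.values):
        interp_im = RegularGridInterpolator((field.x, field.y), field.values.imag, method=method)
        vals += 1j * interp_im(pts)
    return PolarField(radii=radii, phis=phis, values=vals, p=field.p)


def azimuthal_decompose(polar: PolarField, m_max: int) -> MultipoleComponents:
    """Discrete azimuthal Fourier analysis.

    Vt^(m)(r_j) = (1/n_phi) sum_k values(r_j, phi_k) exp(-i m phi_k),
    so a field proportional to exp(+i m phi) has only its +m component
    nonzero.
    """
    n_phi = polar.n_phi
    if n_phi <= 2 * m_max:
        raise AliasingError(
            f"n_phi = {n_phi} cannot resolve m_max = {m_max} (need n_phi > 2 m_max)"
        )
    c = np.fft.fft(polar.values, axis=1) / n_phi   # c[:, m] for m >= 0, c[:, n+m] for m < 0
    ms = np.arange(-m_max, m_max + 1)
    coeffs = np.stack([c[:, m % n_phi] for m in ms])
    return MultipoleComponents(p=polar.p, m_max=m_max, radii=polar.radii, coeffs=coeffs)


def reconstruct_polar(components: MultipoleComponents, n_phi: int) -> PolarField:
    """Synthesis: values(r_j, phi_k) = sum_m Vt^(m)(r_j) exp(+i m phi_k)."""
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    ms = np.arange(-components.m_max, components.m_max + 1)
    basis = np.exp(1j * np.outer(ms, phis))          # (n_m, n_phi)
    values = components.coeffs.T @ basis             # (n_r, n_phi)
    return PolarField(radii=components.radii, phis=phis, values=values, p=components.p)
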