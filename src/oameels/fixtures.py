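"""Analytic synthetic transition potentials with known symmetry.

TD-DFT transition potentials are external inputs; these fixtures stand
in for them with fields whose azimuthal content, parity and chirality
are known in closed form, so every pipeline stage can be validated
end to end:

* ``multipole_cube`` -- separable field A g(r) h(z) trig(m phi) with a
  single azimuthal harmonic (cos, sin, or complex exp), g regular at
  the axis;
* ``dipole_cube`` -- point transition-dipole potential mu.(r-r0)/|r-r0|^3
  with its singularity capped at a core radius;
* ``helical_assembly`` -- point dipoles on a helix with moments tangent
  to it; the screw coupling of z and phi makes |Vt^(+m)| != |Vt^(-m)|
  at p != 0, i.e. a chiral fixture with nonzero dichroism;
* ``mirror_cube`` -- reflection through a plane containing the beam
  axis, for constructing the enantiomeric partner.

Default grids are 64^3 at 0.3 bohr spacing; a fine preset at
0.18897 bohr (0.1 angstrom) exists for convergence studies.  Dummy
hydrogen atoms are attached at dipole sites so centroid-based
recentering is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ResolutionError
from .volumetric import Atom, VolumetricGrid

__all__ = [
    "FixtureSpec",
    "FINE_SPACING",
    "multipole_cube",
    "dipole_cube",
    "helical_assembly",
    "helix_sites",
    "mirror_cube",
]

#: "paper-like" fine grid spacing, 0.1 angstrom in bohr
FINE_SPACING = 0.18897


@dataclass
class FixtureSpec:
    """Parameters of one synthetic potential.

    ``kind`` selects the generator; unrelated fields are ignored.  The
    grid is centered on the coordinate origin unless ``origin`` is
    given.  ``seed`` + ``jitter`` displace dipole/helix sites by
    Gaussian noise (bohr) for non-symmetric variants.
    """

    kind: str = "multipole"
    npoints: int = 64
    spacing: float = 0.3
    origin: Optional[tuple[float, float, float]] = None
    amplitude: float = 1.0
    # multipole parameters
    m: int = 1
    parity: str = "cos"                 # cos | sin | exp
    radial_scale: float = 3.0
    z_sigma: float = 1.5
    # dipole parameters
    moment: tuple[float, float, float] = (1.0, 0.0, 0.0)
    site: tuple[float, float, float] = (0.0, 0.0, 0.0)
    core_radius: Optional[float] = None  # default 2 * spacing
    # helix parameters
    n_sites: int = 6
    helix_radius: float = 2.0
    pitch: float = 1.0
    twist: float = 0.9                   # rad per site
    handedness: int = 1
    moment_scale: float = 1.0
    # stochastic variants
    seed: Optional[int] = None
    jitter: float = 0.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.handedness not in (+1, -1):
            raise ValueError("handedness must be +1 or -1")
        if self.kind == "dipole" and np.linalg.norm(self.moment) == 0:
            raise ValueError("dipole moment must be nonzero")

    def grid_coords(self):
        n, d = self.npoints, self.spacing
        if self.origin is None:
            origin = np.full(3, -(n - 1) * d / 2.0)
        else:
            origin = np.asarray(self.origin, dtype=float)
        axes = [origin[i] + np.arange(n) * d for i in range(3)]
        return origin, axes

    def _extent_check(self, point):
        origin, axes = self.grid_coords()
        for i in range(3):
            if not (axes[i][0] <= point[i] <= axes[i][-1]):
                raise ValueError(f"site {tuple(point)} lies outside the grid")


def _make_grid(spec: FixtureSpec, values: np.ndarray, atoms: list[Atom], label: str) -> VolumetricGrid:
    origin, _ = spec.grid_coords()
    step = np.diag([spec.spacing] * 3)
    return VolumetricGrid(
        origin, step, values, atoms,
        comments=(f"synthetic {label} transition potential", "generated by oameels.fixtures"),
    )


def multipole_cube(spec: FixtureSpec) -> VolumetricGrid:
    """Separable single-harmonic field.

    V(r, phi, z) = A * r^|m| exp(-r^2 / 2 s^2) * h(z) * trig(m phi)
    with h a unit-area Gaussian of width z_sigma and trig one of
    cos/sin/exp (exp yields a complex in-memory field with a pure
    +m azimuthal content; it cannot be written to a cube file).
    Raises :class:`ResolutionError` when the azimuthal feature at the
    radial peak is unresolvable at the grid spacing.
    """
    if spec.kind != "multipole":
        raise ValueError("spec.kind must be 'multipole'")
    m, s = spec.m, spec.radial_scale
    if m != 0:
        r_peak = s * np.sqrt(abs(m))
        if 2.0 * np.pi * r_peak / abs(m) < 6.0 * spec.spacing:
            raise ResolutionError(
                f"azimuthal wavelength at the radial peak "
                f"({2 * np.pi * r_peak / abs(m):.3g} bohr) is unresolvable at "
                f"spacing {spec.spacing:g} bohr"
            )
    _, (x, y, z) = spec.grid_coords()
    rho = np.hypot(x[:, None], y[None, :])
    phi = np.arctan2(y[None, :], x[:, None])
    radial = rho ** abs(m) * np.exp(-(rho**2) / (2.0 * s**2))
    hz = np.exp(-(z**2) / (2.0 * spec.z_sigma**2)) / (spec.z_sigma * np.sqrt(2.0 * np.pi))
    if spec.parity == "cos":
        ang = np.cos(m * phi)
    elif spec.parity == "sin":
        ang = np.sin(m * phi)
    elif spec.parity == "exp":
        ang = np.exp(1j * m * phi)
    else:
        raise ValueError(f"unknown parity {spec.parity!r}")
    values = spec.amplitude * (radial * ang)[:, :, None] * hz[None, None, :]
    return _make_grid(spec, values, [Atom(1, 1.0, np.zeros(3))], f"multipole m={m} ({spec.parity})")


def _dipole_field(x, y, z, site, moment, core_radius):
    """Capped point-dipole potential on the lattice: mu.n / max(d, rc)^2."""
    dx = x[:, None, None] - site[0]
    dy = y[None, :, None] - site[1]
    dz = z[None, None, :] - site[2]
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    proj = moment[0] * dx + moment[1] * dy + moment[2] * dz
    capped = np.maximum(dist, core_radius)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = proj / (dist * capped**2)
    return np.where(dist == 0.0, 0.0, v)


def dipole_cube(spec: FixtureSpec) -> VolumetricGrid:
    """Point transition-dipole potential mu.(r - r0)/|r - r0|^3.

    Values inside the core radius (default 2 * spacing) are replaced by
    the value at the core radius along the same direction, keeping the
    cube finite; in aloof geometry the annulus never samples the core,
    so the cap does not affect rates.
    """
    if spec.kind != "dipole":
        raise ValueError("spec.kind must be 'dipole'")
    site = np.asarray(spec.site, dtype=float)
    if spec.seed is not None and spec.jitter > 0:
        site = site + np.random.default_rng(spec.seed).normal(0.0, spec.jitter, 3)
    spec._extent_check(site)
    rc = spec.core_radius if spec.core_radius is not None else 2.0 * spec.spacing
    _, (x, y, z) = spec.grid_coords()
    values = spec.amplitude * _dipole_field(x, y, z, site, np.asarray(spec.moment, float), rc)
    return _make_grid(spec, values, [Atom(1, 1.0, site)], "point dipole")


def helix_sites(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Site positions and tangent moments of the helical assembly.

    Site j sits at (R cos t_j, R sin t_j, z_j) with
    t_j = handedness * (j - (n-1)/2) * twist and z_j centered on 0;
    each moment is moment_scale times the unit tangent of the helix.
    Flipping the handedness produces the exact mirror image through the
    xz plane.
    """
    n, R, h = spec.n_sites, spec.helix_radius, spec.handedness
    j = np.arange(n) - (n - 1) / 2.0
    theta = h * j * spec.twist
    sites = np.column_stack([R * np.cos(theta), R * np.sin(theta), j * spec.pitch])
    tangents = np.column_stack(
        [
            -R * h * spec.twist * np.sin(theta),
            R * h * spec.twist * np.cos(theta),
            np.full(n, float(spec.pitch)),
        ]
    )
    norms = np.linalg.norm(tangents, axis=1)
    norms[norms == 0] = 1.0
    moments = spec.moment_scale * tangents / norms[:, None]
    if spec.seed is not None and spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        sites = sites + rng.normal(0.0, spec.jitter, sites.shape)
    return sites, moments


def helical_assembly(spec: FixtureSpec) -> VolumetricGrid:
    """Superposition of capped point-dipole potentials on a helix.

    The tangent moments couple the z and phi dependence, so at nonzero
    longitudinal momentum transfer the +m and -m multipole magnitudes
    differ: the fixture is chiral and shows OAM dichroism, with the
    opposite handedness giving the exact sign-flipped spectrum.  With
    pitch = 0 the assembly is planar (even in z) and its dichroism
    vanishes.
    """
    if spec.kind != "helix":
        raise ValueError("spec.kind must be 'helix'")
    sites, moments = helix_sites(spec)
    rc = spec.core_radius if spec.core_radius is not None else 2.0 * spec.spacing
    _, (x, y, z) = spec.grid_coords()
    values = np.zeros((spec.npoints,) * 3)
    atoms = []
    for site, mu in zip(sites, moments):
        spec._extent_check(site)
        values += _dipole_field(x, y, z, site, mu, rc)
        atoms.append(Atom(1, 1.0, site.copy()))
    values *= spec.amplitude
    return _make_grid(spec, values, atoms, f"helix h={spec.handedness:+d}")


_MIRROR_AXES = {"xz": 1, "zx": 1, "yz": 0, "zy": 0}


def mirror_cube(grid: VolumetricGrid, plane: str = "xz") -> VolumetricGrid:
    """Reflect field and atoms through an axis-aligned plane containing
    the beam (z) axis: "xz" flips y, "yz" flips x."""
    axis = _MIRROR_AXES.get(plane)
    if axis is None:
        raise ValueError(f"mirror plane {plane!r} does not contain the z axis")
    n = grid.shape[axis]
    values = np.flip(grid.values, axis=axis).copy()
    origin = grid.origin.copy()
    origin[axis] = -(grid.origin[axis] + (n - 1) * grid.step[axis, axis])
    atoms = []
    for a in grid.atoms:
        pos = a.position.copy()
        pos[axis] = -pos[axis]
        atoms.append(Atom(a.number, a.charge, pos))
    return VolumetricGrid(origin, grid.step.copy(), values, atoms, grid.comments)
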