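"""Volumetric transition potentials on regular grids, Gaussian cube I/O.

A transition potential V_0n(r) is the electrostatic potential generated
by the transition density between the electronic ground state |0> and an
excited state |n>.  Quantum-chemistry codes export it on a regular
Cartesian grid in the Gaussian cube format; this module reads and writes
that format, recenters grids on the nuclear centroid (the beam axis must
pass through the barycenter of the system for the OAM selection rule to
hold) and provides the z-projection used for quick-look maps.

Only orthogonal, axis-aligned grids are supported; the grid z axis is
identified with the beam axis.  Lengths are bohr, potentials hartree/e.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CubeFormatError, UnsupportedGridError
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "Atom",
    "VolumetricGrid",
    "Transition",
    "TransitionSet",
    "read_cube",
    "write_cube",
    "nuclear_centroid",
    "recenter",
    "project_z",
    "read_transition_table",
    "write_transition_table",
]


@dataclass
class Atom:
    """One nucleus: atomic number, nuclear charge, position (bohr)."""

    number: int
    charge: float
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class VolumetricGrid:
    """Scalar field on a regular 3D grid with an atom list.

    ``origin`` is the position of grid point (0, 0, 0); ``step`` holds the
    three axis step vectors as rows.  ``values`` has shape (nx, ny, nz)
    with the z index fastest in file order.  Values are real for cube I/O
    but complex fields are allowed in memory (synthetic fixtures with a
    pure exp(i m phi) azimuthal content are complex).
    """

    origin: np.ndarray
    step: np.ndarray
    values: np.ndarray
    atoms: list[Atom] = field(default_factory=list)
    comments: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.step = np.asarray(self.step, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 3:
            raise UnsupportedGridError("values must be a 3D array")
        if min(self.values.shape) < 2:
            raise UnsupportedGridError("each axis needs at least 2 points")
        if not np.all(np.isfinite(self.values.view(float))):
            raise UnsupportedGridError("grid values must be finite")
        if abs(np.linalg.det(self.step)) < 1e-14:
            raise UnsupportedGridError("axis step vectors are linearly dependent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_orthogonal(self) -> bool:
        off = self.step - np.diag(np.diag(self.step))
        return bool(np.all(np.abs(off) <= 1e-10 * np.abs(np.diag(self.step)).max()))

    def require_orthogonal(self) -> None:
        if not self.is_orthogonal:
            raise UnsupportedGridError(
                "only orthogonal, axis-aligned grids are supported"
            )

    @property
    def spacing(self) -> np.ndarray:
        """Axis step lengths (dx, dy, dz)."""
        return np.linalg.norm(self.step, axis=1)

    def axis_coords(self, axis: int) -> np.ndarray:
        self.require_orthogonal()
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.step[axis, axis]

    @property
    def x_coords(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y_coords(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(2)

    def inscribed_radius(self, center_xy=(0.0, 0.0)) -> float:
        """Largest transverse radius about ``center_xy`` fully inside the grid."""
        cx, cy = center_xy
        x, y = self.x_coords, self.y_coords
        return float(min(cx - x[0], x[-1] - cx, cy - y[0], y[-1] - cy))


# -- cube I/O -------------------------------------------------------------

def _parse_floats(tokens: Sequence[str], line_no: int, path) -> list[float]:
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise CubeFormatError(f"{path}: line {line_no}: {exc}") from None


def read_cube(path) -> VolumetricGrid:
    """Read a Gaussian cube file.

    Both sign conventions of the voxel-count fields are accepted: positive
    counts mean bohr, negative counts mean angstrom (converted to bohr on
    read).  A negative atom count signals a trailing orbital-ID line,
    which is consumed; only single-field cubes are supported.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise CubeFormatError(f"{path}: fewer than 6 header lines")
    comments = (lines[0], lines[1])

    toks = lines[2].split()
    if len(toks) < 4:
        raise CubeFormatError(f"{path}: line 3: expected natoms + origin, got {lines[2]!r}")
    try:
        natoms = int(toks[0])
    except ValueError:
        raise CubeFormatError(f"{path}: line 3: atom count {toks[0]!r} is not an integer") from None
    origin = np.array(_parse_floats(toks[1:4], 3, path))

    counts = []
    step = np.zeros((3, 3))
    for i in range(3):
        toks = lines[3 + i].split()
        if len(toks) < 4:
            raise CubeFormatError(f"{path}: line {4 + i}: malformed axis line {lines[3 + i]!r}")
        try:
            counts.append(int(toks[0]))
        except ValueError:
            raise CubeFormatError(
                f"{path}: line {4 + i}: voxel count {toks[0]!r} is not an integer"
            ) from None
        step[i] = _parse_floats(toks[1:4], 4 + i, path)

    angstrom = any(c < 0 for c in counts)
    counts = [abs(c) for c in counts]
    orbital_mode = natoms < 0
    natoms = abs(natoms)

    atoms = []
    for i in range(natoms):
        idx = 6 + i
        if idx >= len(lines):
            raise CubeFormatError(f"{path}: line {idx + 1}: missing atom line ({natoms} declared)")
        toks = lines[idx].split()
        if len(toks) < 5:
            raise CubeFormatError(f"{path}: line {idx + 1}: malformed atom line {lines[idx]!r}")
        try:
            z = int(toks[0])
        except ValueError:
            raise CubeFormatError(
                f"{path}: line {idx + 1}: malformed atom line (got {toks[0]!r} "
                f"where an element number was expected; {natoms} atoms declared)"
            ) from None
        charge, *pos = _parse_floats(toks[1:5], idx + 1, path)
        atoms.append(Atom(z, charge, np.array(pos)))

    idx = 6 + natoms
    if orbital_mode:
        if idx >= len(lines):
            raise CubeFormatError(f"{path}: missing orbital-ID line")
        orb = lines[idx].split()
        try:
            norb = int(orb[0])
        except (IndexError, ValueError):
            raise CubeFormatError(f"{path}: line {idx + 1}: malformed orbital-ID line") from None
        if norb != 1:
            raise CubeFormatError(f"{path}: {norb} orbitals per point; only single-field cubes supported")
        idx += 1

    flat = []
    for line_no, line in enumerate(lines[idx:], start=idx + 1):
        flat.extend(_parse_floats(line.split(), line_no, path))
    expected = counts[0] * counts[1] * counts[2]
    if len(flat) != expected:
        raise CubeFormatError(
            f"{path}: expected {expected} values ({counts[0]}x{counts[1]}x{counts[2]}), "
            f"found {len(flat)} (truncated or padded data section)"
        )
    values = np.array(flat).reshape(counts)

    if angstrom:
        origin = origin * BOHR_PER_ANGSTROM
        step = step * BOHR_PER_ANGSTROM
        for a in atoms:
            a.position = a.position * BOHR_PER_ANGSTROM

    grid = VolumetricGrid(origin, step, values, atoms, comments)
    grid.require_orthogonal()
    return grid


def write_cube(grid: VolumetricGrid, path) -> None:
    """Write a grid as a Gaussian cube file (positive counts, bohr)."""
    if np.iscomplexobj(grid.values):
        raise ValueError("cannot write a complex-valued field to a cube file")
    path = Path(path)
    nx, ny, nz = grid.shape
    out = [grid.comments[0], grid.comments[1]]
    out.append(
        f"{len(grid.atoms):5d} {grid.origin[0]:12.6f} {grid.origin[1]:12.6f} {grid.origin[2]:12.6f}"
    )
    for i, n in enumerate((nx, ny, nz)):
        s = grid.step[i]
        out.append(f"{n:5d} {s[0]:12.6f} {s[1]:12.6f} {s[2]:12.6f}")
    for a in grid.atoms:
        p = a.position
        out.append(f"{a.number:5d} {a.charge:12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}")
    vals = grid.values.reshape(nx * ny, nz)
    for row in vals:
        for k in range(0, nz, 6):
            out.append(" ".join(f"{v:13.6E}" for v in row[k:k + 6]))
    path.write_text("\n".join(out) + "\n")


# -- geometry -------------------------------------------------------------

def nuclear_centroid(grid: VolumetricGrid) -> np.ndarray:
    """Unweighted geometric centroid of the nuclear positions (bohr).

    This is the point the beam axis is centered on; decentering modifies
    the OAM selection rule, so spectra are always computed about it.
    """
    if not grid.atoms:
        raise ValueError("centroid undefined: grid has no atoms")
    return np.mean([a.position for a in grid.atoms], axis=0)


def recenter(grid: VolumetricGrid, point) -> VolumetricGrid:
    """Translate the frame so that ``point`` maps to the coordinate origin."""
    point = np.asarray(point, dtype=float).reshape(3)
    atoms = [Atom(a.number, a.charge, a.position - point) for a in grid.atoms]
    return VolumetricGrid(grid.origin - point, grid.step.copy(), grid.values, atoms, grid.comments)


def project_z(grid: VolumetricGrid) -> np.ndarray:
    """Trapezoidal integral of the field along z, on the (x, y) lattice."""
    grid.require_orthogonal()
    return np.trapezoid(grid.values, x=grid.z_coords, axis=2)


# -- transition sets ------------------------------------------------------

@dataclass
class Transition:
    """One electronic excitation: index, energy (eV), optional oscillator
    strength, and its transition potential (in memory or as a cube path)."""

    index: int
    energy_ev: float
    grid: Optional[VolumetricGrid] = None
    cube_path: Optional[Path] = None
    oscillator_strength: Optional[float] = None

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError(f"transition {self.index}: energy must be positive")
        if self.oscillator_strength is not None and self.oscillator_strength < 0:
            raise ValueError(f"transition {self.index}: oscillator strength must be >= 0")

    def load(self) -> VolumetricGrid:
        if self.grid is None:
            if self.cube_path is None:
                raise ValueError(f"transition {self.index}: no grid and no cube path")
            self.grid = read_cube(self.cube_path)
        return self.grid


@dataclass
class TransitionSet:
    entries: list[Transition]

    def __post_init__(self):
        indices = [t.index for t in self.entries]
        if len(set(indices)) != len(indices):
            raise ValueError("transition indices must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def read_transition_table(path, base_dir=None) -> TransitionSet:
    """Read a delimited table with columns n, energy_eV,
    oscillator_strength (optional), cube_path (optional)."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path}: no transitions")
    entries = []
    for _, row in df.iterrows():
        f = row.get("oscillator_strength")
        cube = row.get("cube_path")
        entries.append(
            Transition(
                index=int(row["n"]),
                energy_ev=float(row["energy_eV"]),
                cube_path=(base / str(cube)) if isinstance(cube, str) else None,
                oscillator_strength=None if f is None or pd.isna(f) else float(f),
            )
        )
    return TransitionSet(entries)


def write_transition_table(transitions: TransitionSet, path) -> None:
    rows = []
    for t in transitions:
        rows.append(
            {
                "n": t.index,
                "energy_eV": t.energy_ev,
                "oscillator_strength": t.oscillator_strength,
                "cube_path": str(t.cube_path) if t.cube_path is not None else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
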