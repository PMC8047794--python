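"""Shared builders for the test suite.

All fixtures are generated programmatically; no data files.
"""

import numpy as np
import pytest

from oameels import VolumetricGrid


def grid_from_function(fn, n=32, spacing=0.5, atoms=None):
    """Centered cubic grid with values fn(X, Y, Z)."""
    origin = -(n - 1) * spacing / 2.0
    x = y = z = origin + np.arange(n) * spacing
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return VolumetricGrid(
        [origin] * 3, np.diag([spacing] * 3), fn(X, Y, Z), atoms or [], ("test", "grid")
    )


def chiral_blob_grid(n=32, spacing=0.5, n_blobs=4, radius=1.5, pitch=1.0,
                     twist=0.9, width=1.2):
    """Smooth chiral field: alternating-sign Gaussian blobs on a helix.

    Infinitely differentiable everywhere (unlike the capped point-dipole
    fixtures), so interpolation converges at full order; used for the
    oracle-equivalence checks.
    """

    def fn(X, Y, Z):
        V = np.zeros_like(X)
        for j in range(n_blobs):
            t = j - (n_blobs - 1) / 2.0
            cx, cy, cz = radius * np.cos(twist * t), radius * np.sin(twist * t), pitch * t
            V += (-1.0) ** j * np.exp(
                -((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2.0 * width**2)
            )
        return V

    return grid_from_function(fn, n, spacing)


@pytest.fixture
def compact_beam():
    """Annulus small enough to sit inside a 32^3 half-bohr grid."""
    from oameels import BeamParameters

    return BeamParameters(r0=3.0, dr=1.0)
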