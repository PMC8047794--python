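"""Exception types raised by the volumetric / decomposition pipeline."""


class CubeFormatError(ValueError):
    """A Gaussian cube file violates the format convention."""


class UnsupportedGridError(ValueError):
    """The volumetric grid is skewed or otherwise unusable (only
    orthogonal, axis-aligned grids are supported)."""


class OutOfExtentError(ValueError):
    """A polar resampling request reaches outside the Cartesian grid."""


class AliasingError(ValueError):
    """The azimuthal sampling cannot resolve the requested multipole order."""


class ResolutionError(ValueError):
    """A synthetic fixture's angular feature is unresolvable at the
    requested grid spacing."""
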