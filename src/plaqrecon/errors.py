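"""Exception hierarchy shared across the package."""


class PlaqreconError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(PlaqreconError):
    """A contour or cross-section violates a geometric invariant."""


class ReconstructionError(PlaqreconError):
    """Backside reconstruction could not produce a valid polygon."""


class SpecError(PlaqreconError):
    """A synthetic plaque specification is infeasible."""


class FEError(PlaqreconError):
    """Finite-element meshing or solution failure."""
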