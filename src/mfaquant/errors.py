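"""Exception hierarchy for the MFA quantification pipeline."""


class MFAError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(MFAError, ValueError):
    """Pad layout is geometrically invalid (overlap, out of bounds)."""


class NoBackgroundRegionError(LayoutError):
    """The pad layout leaves no inter-pad pixels to estimate a background from."""


class UnsupportedGeometryError(MFAError, ValueError):
    """Duplex loading geometry is not one of the supported modes."""


class NumericalIntegrationError(MFAError, RuntimeError):
    """Quadrature of the competing-hazards density did not converge."""


class InsufficientDataError(MFAError, ValueError):
    """Too few conditions/points for the requested fit or comparison."""


class DegenerateModelError(MFAError, ValueError):
    """A linear NF model with zero slope cannot be solved for a target NF."""


class NoMatchError(MFAError, ValueError):
    """No cross-motif condition pair is equal within errors."""


class ComparisonUndefinedError(MFAError, ValueError):
    """Equality-within-errors is undefined for zeroed or failed estimates."""
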