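"""Exception hierarchy for phylosample."""


class PhylosampleError(Exception):
    """Base class for all package errors."""


class NewickParseError(PhylosampleError):
    """Malformed newick input; message names the location when known."""


class TreeValidationError(PhylosampleError):
    """Tree violates a structural invariant (e.g. duplicate tip labels)."""


class UnknownTipError(PhylosampleError, KeyError):
    """A requested tip label is not present in the tree."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(f"unknown tip label(s): {', '.join(self.offenders)}")


class SchemeDomainError(PhylosampleError, ValueError):
    """Sampling-scheme parameters outside their valid domain."""


class InsufficientDataError(PhylosampleError, ValueError):
    """Not enough data points for a fit."""


class UndefinedDistanceError(PhylosampleError, ZeroDivisionError):
    """A distance or normalization is undefined (zero denominator)."""


class UnsupportedSamplerError(PhylosampleError, NotImplementedError):
    """The scheme has no generative sampler (analytic results only)."""
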