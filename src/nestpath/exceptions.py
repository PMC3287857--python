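"""Exception hierarchy for nestpath.

All errors raised by the package derive from :class:`NestpathError` so that
callers (and the CLI) can distinguish validation problems from numerical
failures.
"""


class NestpathError(Exception):
    """Base class for all nestpath errors."""


class DataFormatError(NestpathError):
    """Malformed input file or out-of-range genotype code."""


class AlignmentError(NestpathError):
    """Subject identifiers do not line up across input tables."""


class MappingError(NestpathError):
    """A SNP has no gene assignment (or an otherwise broken gene map)."""


class EmptyPathwayError(NestpathError):
    """No polymorphic SNPs (or no rare SNPs) remain after filtering."""


class DesignError(NestpathError):
    """Rank-deficient or otherwise unusable fixed-effects design."""


class ConvergenceError(NestpathError):
    """An iterative fit failed to converge within its iteration cap."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SeparationError(NestpathError):
    """Quasi-complete separation detected in a binary-trait fit."""


class SizeError(NestpathError):
    """Problem too large for an exact (oracle) routine."""
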