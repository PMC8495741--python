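"""Exception hierarchy shared across the package."""


class ParalogDivergeError(Exception):
    """Base class for all package errors."""


class FormatError(ParalogDivergeError):
    """Malformed input file (ragged alignment, missing branch length, ...)."""


class ValidationError(ParalogDivergeError):
    """Input violates a domain invariant (negative counts, r > N, ...)."""


class TopologyError(ParalogDivergeError):
    """Gene tree conflicts with the master topology after pruning."""


class InsufficientDataError(ParalogDivergeError):
    """Too few branches/cultures/sequences for the requested estimate."""


class NoRootError(ParalogDivergeError):
    """The implicit mutation-rate equation has no admissible root."""
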