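"""Exception hierarchy for ippca."""


class IppcaError(Exception):
    """Base class for all ippca errors."""


class UsageError(IppcaError):
    """Invalid arguments or configuration supplied by the caller."""


class ParseError(IppcaError):
    """A genotype file could not be parsed; the message names the line."""


class StructuralError(IppcaError):
    """A parsed file violates a structural constraint (e.g. ragged marker counts)."""


class NoVariationError(IppcaError):
    """All individuals are identical: the spectrum carries no variance."""


class CriterionError(IppcaError):
    """A structure criterion cannot be evaluated on the given spectrum."""
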