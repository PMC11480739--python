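"""Exception hierarchy shared across the toolkit."""


class SnpDeskError(Exception):
    """Base class for all toolkit errors."""


class VcfParseError(SnpDeskError, ValueError):
    """Malformed VCF header or record."""


class UnsupportedInputError(SnpDeskError, ValueError):
    """Input is well-formed but lacks something the toolkit requires (e.g. GT)."""


class OrderingError(SnpDeskError, ValueError):
    """A site stream violated the position-sorted precondition."""


class ConsistencyError(SnpDeskError, ValueError):
    """Inputs disagree where they must agree (samples, reference alleles)."""


class DomainError(SnpDeskError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class FilterParseError(SnpDeskError, ValueError):
    """Filter expression could not be parsed or used an unknown tag."""
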