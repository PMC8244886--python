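"""Exception hierarchy for hapnetdiv."""


class HapnetError(Exception):
    """Base class for all hapnetdiv errors."""


class AlignmentError(HapnetError):
    """Malformed or inconsistent sequence alignment input."""


class PopulationMapError(HapnetError):
    """Population map references individuals absent from the alignment."""


class NetworkValidationError(HapnetError):
    """A haplotype network violates its structural invariants."""


class DegenerateNetworkError(HapnetError):
    """Fewer than two haplotypes (or individuals): no network can be built."""


class UndefinedMetricError(HapnetError):
    """A diversity metric was requested outside its domain (e.g. n < 2)."""


class SpecError(HapnetError):
    """Invalid synthetic-network specification."""
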