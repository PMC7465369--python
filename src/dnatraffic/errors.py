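"""Exception hierarchy for the dnatraffic package."""


class DnatrafficError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DnatrafficError):
    """A structure file could not be parsed under the named standard."""


class EmptyModelError(DnatrafficError):
    """A parsed structure contained no atoms."""


class ParameterError(DnatrafficError, ValueError):
    """An argument violated a documented precondition."""


class SelectorError(DnatrafficError, LookupError):
    """A chain/residue selector did not resolve in the model."""


class NonNucleotideError(DnatrafficError, TypeError):
    """A DNA segment selector pointed at a non-nucleotide residue."""


class MissingAtomError(DnatrafficError):
    """A named atom required by a selection is absent from a residue."""


class RankError(DnatrafficError):
    """A point set is too degenerate (collinear) for superposition."""


class IntegrationError(DnatrafficError):
    """The ODE solver failed; carries solver diagnostics in the message."""


class GenerationError(DnatrafficError):
    """A synthetic fixture could not be built with self-consistent geometry."""
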