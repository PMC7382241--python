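"""Exception hierarchy shared across the package."""


class TernalyzeError(Exception):
    """Base class for all package errors."""


class FormatError(TernalyzeError):
    """Structure file could not be parsed."""


class EmptyStructureError(FormatError):
    """Parsed file contains no atoms."""


class MappingError(TernalyzeError):
    """A role map references a chain or residue group absent from the structure."""


class CoverageError(TernalyzeError):
    """Atoms left without a role after annotation."""


class ConfigurationError(TernalyzeError):
    """Unknown named configuration (radii set, hydrophobicity scale, ring table)."""


class GeometryError(TernalyzeError):
    """A geometric construction is unrealizable or degenerate."""


class PairingError(TernalyzeError):
    """Atom/residue selections cannot be paired for superposition."""


class ConditioningError(TernalyzeError):
    """Degenerate (e.g. collinear) input to a numerical procedure."""


class UndefinedResultError(TernalyzeError):
    """The requested quantity is undefined for the given input."""


class ConvergenceError(TernalyzeError):
    """An iterative solver failed to reach the requested residual."""
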