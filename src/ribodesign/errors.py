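"""Exception hierarchy used across the package."""


class RibodesignError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(RibodesignError, ValueError):
    """Invalid nucleotide sequence (alphabet, length, mask)."""


class StructureError(RibodesignError, ValueError):
    """Invalid dot-bracket structure or incompatible sequence/structure pair."""


class SpecError(RibodesignError, ValueError):
    """Inconsistent or incomplete gate specification."""


class CapabilityError(RibodesignError, RuntimeError):
    """Request exceeds what the selected engine can compute (size, strand count)."""


class ParameterError(RibodesignError, ValueError):
    """Invalid numerical parameter (e.g. non-positive RT)."""


class InitializationError(RibodesignError, RuntimeError):
    """Random initialization could not satisfy the constraints."""


class MoveError(RibodesignError, RuntimeError):
    """No legal mutation proposal found within the resample budget."""


class FitError(RibodesignError, ValueError):
    """Degenerate regression input (too few points, zero variance)."""
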