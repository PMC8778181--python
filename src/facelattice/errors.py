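"""Exception hierarchy shared across the package."""


class FaceLatticeError(Exception):
    """Base class for all package errors."""


class InputError(FaceLatticeError, ValueError):
    """Malformed or out-of-contract input data."""


class DegenerateGeometryError(FaceLatticeError, ValueError):
    """Landmark geometry that admits no normalization (zero-length nose)."""


class ParameterError(FaceLatticeError, ValueError):
    """Invalid metric parameters (negative or non-finite weights)."""


class StructuralError(FaceLatticeError, ValueError):
    """Tree topology mismatch between operands."""


class LabelError(FaceLatticeError, ValueError):
    """Inconsistent or unknown class labels."""


class EncodingError(FaceLatticeError, ValueError):
    """Chromosome of wrong length or out-of-bound genes."""


class ConfigurationError(FaceLatticeError, ValueError):
    """Infeasible run configuration (folds, population sizes, ...)."""


class StateError(FaceLatticeError, RuntimeError):
    """Operation requires a fitted model or assigned states."""
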