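"""Exception hierarchy shared across the package.

Input problems (bad parameters, malformed data, misaligned inputs) are
``ValueError`` subclasses; problems arising during model fitting are
``RuntimeError`` subclasses so callers can distinguish "fix your input"
from "the optimizer gave up".
"""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class DataError(ValueError):
    """Input data violate a structural requirement (e.g. meth > total)."""


class AlignmentError(ValueError):
    """Two inputs that must share an index (individuals, loci) do not."""


class FitError(RuntimeError):
    """A model cannot be fit (rank-deficient design, degenerate data)."""


class ConvergenceError(RuntimeError):
    """An optimizer or test failed its internal consistency checks."""


class StateError(RuntimeError):
    """An operation was called on an object in the wrong state."""
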