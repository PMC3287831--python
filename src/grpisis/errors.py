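"""Exception and warning types shared across the package."""


class GrpisisError(Exception):
    """Base class for all package-specific errors."""


class InputError(GrpisisError, ValueError):
    """Invalid arguments: dimension mismatches, out-of-range parameters."""


class ParseError(GrpisisError, ValueError):
    """A text table or VCF could not be parsed."""


class AlignmentError(GrpisisError, ValueError):
    """Sample identifiers disagree across input tables."""


class DegenerateFitError(GrpisisError, ValueError):
    """A least-squares fit has fewer than one residual degree of freedom,
    or the response carries no variance to fit."""


class EmptyDesignError(GrpisisError, ValueError):
    """A filtering step removed every SNP column."""


class ConvergenceError(GrpisisError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class CollinearityWarning(UserWarning):
    """A requested fit was rank deficient; a minimum-norm solution was used."""
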