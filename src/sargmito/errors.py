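"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`SargmitoError`, so callers (and the CLI) can distinguish bad input
(:class:`ValidationError`, exit code 2) from a failing pipeline stage
(:class:`StageError`, exit code 3).
"""


class SargmitoError(Exception):
    """Base class for all package errors."""


class FormatError(SargmitoError):
    """A file does not conform to its declared format."""


class ValidationError(SargmitoError):
    """Input values violate a documented precondition or invariant."""


class CollinearityError(ValidationError):
    """Sequences passed to a columnwise comparison have unequal lengths."""


class InfeasibleConstraintError(SargmitoError):
    """No codon/strand/frame assignment satisfies an amino-acid chain."""


class AmplificationError(SargmitoError):
    """In-silico PCR produced zero or more than one product."""

    def __init__(self, message: str, n_products: int = 0):
        super().__init__(message)
        self.n_products = n_products


class AnnotationError(SargmitoError):
    """A variant cannot be annotated against the gene model."""


class AmbiguityError(AnnotationError):
    """A position is covered by more than one feature."""


class StageError(SargmitoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
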