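"""Exception hierarchy shared across the package."""


class UHSRError(Exception):
    """Base class for all package errors."""


class SchemaError(UHSRError, ValueError):
    """A table, feature vector or report does not match the expected schema."""


class ValidationError(UHSRError, ValueError):
    """A value violates a documented invariant (e.g. Rf outside [0, 1])."""


class SmilesParseError(UHSRError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


class ConfigError(UHSRError, ValueError):
    """An invalid configuration (overlapping groups, empty primitive set, ...)."""


class TrainingError(UHSRError, RuntimeError):
    """Training aborted (non-finite loss, empty data, ...)."""


class EvaluationError(UHSRError, ValueError):
    """Expression evaluation failed (unbound variable, domain error, ...)."""


class UnsupportedFormError(UHSRError, ValueError):
    """An expression does not have the algebraic form an operation requires."""
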