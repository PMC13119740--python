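"""Exception hierarchy.

The CLI maps these onto distinct exit codes so that batch callers can tell
configuration mistakes from bad data from identifier clashes.
"""


class MinmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MinmarkError):
    """Invalid or self-contradictory configuration (exit code 2)."""


class DataError(MinmarkError):
    """Input data is unusable (exit code 3)."""


class CodingError(DataError):
    """A token in a genotype file cannot be resolved under the declared dialect."""


class UndefinedFrequencyError(DataError):
    """Allele frequencies requested for a marker with no non-missing calls."""


class IdentityError(MinmarkError):
    """Duplicate or unknown accession/marker identifiers (exit code 4)."""


class PipelineStageError(MinmarkError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
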