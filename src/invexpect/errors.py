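"""Exception hierarchy shared across the package.

Validation problems (bad input data, bad configuration) and stage failures
(an otherwise valid run that cannot proceed) are kept distinct so the CLI
can map them to different exit codes.
"""


class InvexpectError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(InvexpectError):
    """A required column or configuration key is missing or malformed."""


class ValidationError(InvexpectError):
    """Input data violates a documented invariant (bad region code, bad range)."""


class StageError(InvexpectError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
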