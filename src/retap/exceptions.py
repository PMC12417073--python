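"""Exception hierarchy for retap.

Every error a user can trigger through the CLI derives from
:class:`RetapError` so the entry point can report a clean message and a
nonzero exit code without a traceback.
"""


class RetapError(Exception):
    """Base class for all retap errors."""


class ModelFormatError(RetapError):
    """The model file could not be parsed, or uses an unsupported dialect."""


class ModelValidationError(RetapError):
    """The parsed model violates a structural invariant (e.g. duplicate ids)."""


class ReactionLookupError(RetapError, KeyError):
    """A user-supplied reaction id does not resolve in the model."""

    def __init__(self, query: str, suggestions: list[str]):
        self.query = query
        self.suggestions = suggestions
        hint = f"; closest ids: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"no reaction with id {query!r}{hint}")


class InfeasibleModelError(RetapError):
    """An LP stage was infeasible under the enforced bounds."""


class ScanError(RetapError):
    """The enforced-production scan cannot be run (e.g. zero yield)."""


class PipelineError(RetapError):
    """A pipeline stage failed; the message names the stage."""
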