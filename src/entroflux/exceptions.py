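"""Exception hierarchy.

All entroflux errors derive from :class:`EntrofluxError` so callers can catch
broadly; solver non-convergence is *not* an exception (it is reported through
``FluxSolution.status``) because batch runs over many transcriptomes must
continue past individual failures.
"""


class EntrofluxError(Exception):
    """Base class for all entroflux errors."""


class ModelFormatError(EntrofluxError):
    """A model file could not be parsed under the requested dialect."""


class ValidationError(EntrofluxError):
    """An in-memory object violates a structural invariant."""


class UnknownReactionError(EntrofluxError, KeyError):
    """A reaction identifier does not exist in the network."""


class ExpressionParseError(EntrofluxError):
    """An expression table is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class GPRSyntaxError(EntrofluxError):
    """A gene-protein-reaction rule does not parse as an and/or tree."""


class MappingError(EntrofluxError):
    """Expression could not be mapped onto reactions (e.g. no GPR hits)."""


class UnboundedProblemError(EntrofluxError):
    """An optimization is unbounded; usually missing finite flux bounds."""
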