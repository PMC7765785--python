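"""Exception hierarchy shared by every pipeline stage.

``exit_code`` mirrors the CLI contract: 2 for input/format problems,
3 for empty-result conditions that are not format errors.
"""


class MirnetError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class FormatError(MirnetError):
    """An input file does not conform to the expected dialect."""

    exit_code = 2


class MissingColumnError(FormatError):
    """A required column is absent from a tabular input."""


class TissueNotFoundError(FormatError):
    """The requested tissue has no rows in the expression table."""

    def __init__(self, tissue, available):
        self.tissue = tissue
        self.available = sorted(available)
        super().__init__(
            f"tissue {tissue!r} not found in expression table; "
            f"available tissues: {', '.join(self.available)}"
        )


class EmptyResultError(MirnetError):
    """A stage produced no usable result (not a format problem)."""

    exit_code = 3


class NoExpressedTargetsError(EmptyResultError):
    """No target gene is expressed in the requested tissue."""


class EmptyNetworkError(EmptyResultError):
    """An operation that needs a non-empty network received none."""


class DisconnectedGraphError(MirnetError):
    """An operation that requires a connected graph received a disconnected one."""

    exit_code = 2


class StageError(MirnetError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        self.exit_code = getattr(cause, "exit_code", 1)
        super().__init__(f"stage {stage!r} failed: {cause}")
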