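"""Exception hierarchy for the msreach pipeline."""


class MsreachError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MsreachError, ValueError):
    """A parameter or input value lies outside its mathematical domain."""


class FormatError(MsreachError, ValueError):
    """An input series violates a structural contract (timing, shape, units)."""


class DegenerateThresholdError(DomainError):
    """Velocity-threshold estimation collapsed (zero spread) on one axis."""

    def __init__(self, axis: str):
        self.axis = axis
        super().__init__(
            f"degenerate velocity threshold: zero median-based SD on {axis} axis"
        )


class SegmentationError(MsreachError):
    """No hand-movement onset/offset satisfying the criteria could be found."""


class NoTrialEndError(MsreachError):
    """The condition-specific trial-end rule was never satisfied."""


class PipelineOrderError(MsreachError):
    """A stage was invoked before a required upstream derived field exists."""


class BalanceError(MsreachError):
    """A repeated-measures table is incomplete (missing participant cells)."""


class ValidationError(MsreachError):
    """A run configuration failed validation; lists the offending fields."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


class EmptyReportError(MsreachError):
    """Report generation was requested for an empty result set."""
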