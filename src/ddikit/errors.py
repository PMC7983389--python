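"""Exception hierarchy for the ddikit pipeline.

Every error raised by the library derives from :class:`DdikitError`, so
callers (including the CLI) can distinguish pipeline failures from
programming errors.
"""


class DdikitError(Exception):
    """Base class for all ddikit errors."""


class ConfigurationError(DdikitError):
    """A scenario or run configuration violates its invariants."""


class MalformedCodeError(DdikitError):
    """An ICD-10 code string cannot be normalized.

    Carries the offending raw string in ``raw``.
    """

    def __init__(self, raw: str, detail: str = ""):
        self.raw = raw
        msg = f"malformed ICD-10 code: {raw!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class InvalidCountError(DdikitError):
    """A code-count table contains a non-positive count."""


class EmptyInputError(DdikitError):
    """An operation requiring at least one record received none."""


class ReferentialIntegrityError(DdikitError):
    """Cases reference region ids absent from the region table.

    ``offenders`` lists the unknown region ids.
    """

    def __init__(self, offenders, what: str = "region_id"):
        self.offenders = sorted(set(offenders))
        super().__init__(
            f"unknown {what} values referenced: {self.offenders[:20]}"
            + (" ..." if len(self.offenders) > 20 else "")
        )


class InfeasibleTargetError(DdikitError):
    """A calibration target entropy lies outside the attainable range."""


class SchemaError(DdikitError):
    """An input table is missing required columns."""


class InsufficientDataError(DdikitError):
    """Too few data points for the requested fit."""


class FitFailureError(DdikitError):
    """A nonlinear or GLM fit failed to converge.

    ``best`` holds the best attempt (may be None).
    """

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class DegenerateFitError(DdikitError):
    """The data admit no identifiable fit (e.g. all counts zero)."""


class InvalidParameterError(DdikitError):
    """Model parameters violate their domain constraints."""
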