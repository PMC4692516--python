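"""Exception hierarchy for dceleak.

All domain errors derive from :class:`DceleakError` so callers (and the CLI)
can catch one base class and emit a structured error record.
"""


class DceleakError(Exception):
    """Base class for all dceleak errors."""

    def to_dict(self) -> dict:
        return {"error": type(self).__name__, "message": str(self)}


class InvalidParameterError(DceleakError, ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class NonPhysicalSignalRatioError(DceleakError, ValueError):
    """VFA signal ratio outside the interval mapping to a positive, finite T1."""


class NoSolutionError(DceleakError, ValueError):
    """Signal-to-concentration inversion found no root within the bracket."""

    def __init__(self, message: str, enhancement: float | None = None):
        super().__init__(message)
        self.enhancement = enhancement

    def to_dict(self) -> dict:
        d = super().to_dict()
        if self.enhancement is not None:
            d["enhancement"] = self.enhancement
        return d


class FitFailureError(DceleakError, RuntimeError):
    """All optimisation starts failed, or a fit is degenerate."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []

    def to_dict(self) -> dict:
        d = super().to_dict()
        if self.diagnostics:
            d["diagnostics"] = self.diagnostics
        return d


class CurveFormatError(DceleakError, ValueError):
    """A curve file is malformed or violates curve invariants."""
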