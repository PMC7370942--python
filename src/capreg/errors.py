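"""Exception hierarchy.

Every error carries a short machine-parsable ``code`` so the CLI can report
failures uniformly (``error code=<code>: <message>``).
"""


class CapRegError(Exception):
    """Base class for all capreg errors."""

    code = "error"


class InvalidParameterError(CapRegError, ValueError):
    code = "invalid-parameter"


class DegenerateInputError(CapRegError, ValueError):
    code = "degenerate-input"


class IncompleteSceneError(CapRegError, ValueError):
    code = "incomplete-scene"


class InvalidCameraError(CapRegError, ValueError):
    code = "invalid-camera"


class ContractViolationError(CapRegError, ValueError):
    code = "contract-violation"


class IncompleteLandmarksError(CapRegError, ValueError):
    code = "incomplete-landmarks"


class DegeneratePolygonError(CapRegError, ValueError):
    code = "degenerate-polygon"


class InsufficientPointsError(CapRegError, ValueError):
    code = "insufficient-points"


class LabelingFailureError(CapRegError, RuntimeError):
    code = "labeling-failure"


class IncompleteModelError(CapRegError, ValueError):
    code = "incomplete-model"


class DegenerateModelError(CapRegError, ValueError):
    code = "degenerate-model"


class MissingFiducialError(CapRegError, ValueError):
    code = "missing-fiducial"


class InsufficientFiducialsError(CapRegError, ValueError):
    code = "insufficient-fiducials"


class NoOverlapError(CapRegError, ValueError):
    code = "no-overlap"


class InsufficientDataError(CapRegError, ValueError):
    code = "insufficient-data"


class DegenerateTestError(CapRegError, ValueError):
    code = "degenerate-test"


class DegenerateRegressionError(CapRegError, ValueError):
    code = "degenerate-regression"


class DomainError(CapRegError, ValueError):
    code = "domain-error"


class PlyParseError(CapRegError, ValueError):
    """Malformed PLY input; names the offending header line."""

    code = "ply-parse-error"

    def __init__(self, message: str, line_number: int | None = None,
                 line: str | None = None):
        self.line_number = line_number
        self.line = line
        if line_number is not None:
            message = f"{message} (line {line_number}: {line!r})"
        super().__init__(message)


class MissingColorError(CapRegError, ValueError):
    code = "missing-color"


class PipelineStageError(CapRegError, RuntimeError):
    """Wraps an error raised inside a pipeline stage with remediation hint."""

    code = "pipeline-stage"

    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        self.stage = stage
        self.hint = hint
        msg = f"stage '{stage}' failed: {cause}"
        if hint:
            msg += f" — {hint}"
        super().__init__(msg)
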