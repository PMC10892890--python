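"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`insulametrics.cli`; library code
raises these and never calls ``sys.exit``.
"""


class InsulametricsError(Exception):
    """Base class for all package errors."""


class GridFormatError(InsulametricsError):
    """Unparseable or internally inconsistent grid file (ragged rows, bad header)."""


class DegenerateInputError(InsulametricsError):
    """Input is structurally valid but too small/empty for the operation."""


class CoverageError(InsulametricsError):
    """A survey disc (or required radius) extends beyond the raster extent."""


class ValidationError(InsulametricsError):
    """A table or record violates a dataset invariant (e.g. endemics > spp)."""


class BoundaryValueError(ValidationError):
    """Proportions exactly 0 or 1 passed to a beta-distributed response."""


class ConvergenceError(InsulametricsError):
    """An ML fit failed to converge; carries the optimizer trace message."""


class StageError(InsulametricsError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
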