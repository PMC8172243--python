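"""Exception hierarchy shared across the pipeline stages."""


class PhotoscratchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhotoscratchError, ValueError):
    """Invalid configuration value (non-positive rate, carrier at Nyquist, ...)."""


class ParseError(PhotoscratchError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        self.line = line
        self.column = column
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class DegenerateFitError(PhotoscratchError, ValueError):
    """The isosbestic scaling fit is not identifiable (constant control, too few samples)."""


class DegenerateBaselineError(PhotoscratchError, ValueError):
    """The dF/F divisor is near zero or negative; suggests the fitted-control convention."""


class EmptyResultError(PhotoscratchError, ValueError):
    """An operation retained no data (e.g. every peri-event trial excluded)."""


class ZeroVarianceError(PhotoscratchError, ValueError):
    """A z-score reference window has zero variance; names the offending trial."""
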