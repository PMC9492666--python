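"""Exception hierarchy.

Every failure path raises a subclass of :class:`SynscreenError` so the CLI can
turn any library error into a one-line, machine-parsable message and a nonzero
exit code.
"""


class SynscreenError(Exception):
    """Base class for all synscreen errors."""


class ConfigError(SynscreenError):
    """Invalid simulation or run configuration."""


class NormalizationError(SynscreenError):
    """Plate cannot be normalized (e.g. vehicle mean <= blank mean)."""


class PlateRejectedError(NormalizationError):
    """A plate lacks the control wells required for normalization."""


class ScreenError(SynscreenError):
    """Screen-level failure (e.g. inducer-alone record absent)."""


class UndefinedSIError(ScreenError):
    """Synergy Index undefined: inducer-alone effect below epsilon."""


class FitError(SynscreenError):
    """Median-effect fit impossible (too few usable points)."""


class ModelViolationError(FitError):
    """Fitted slope is non-positive: data violate the median-effect model."""


class UndefinedDoseError(SynscreenError):
    """Effect level of 0 or 1 has no finite dose under the model."""


class MeasurementOrderError(SynscreenError):
    """Caliper diameters out of order (shortest exceeds longest)."""


class UndefinedTGIError(SynscreenError):
    """TGI undefined: control group did not grow (Vc <= V0)."""


class TableError(SynscreenError):
    """Base class for tabular I/O errors."""


class MissingColumnError(TableError):
    """Input file header lacks a required column."""


class EmptyTableError(TableError):
    """Input file contains no data rows."""


class MalformedRowError(TableError):
    """One or more data rows fail schema validation."""


class PipelineError(SynscreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
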