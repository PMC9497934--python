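"""Exception hierarchy.

All toolkit errors derive from :class:`DqekitError` so callers can catch the
package's failures with a single clause while still distinguishing registry
misses, geometry problems and numerical degeneracies.
"""


class DqekitError(Exception):
    """Base class for all dqekit errors."""


class RegistryMissError(DqekitError, KeyError):
    """Lookup of an unregistered beam quality or detector name."""

    def __init__(self, name: str, valid: list[str]):
        self.name = name
        self.valid = list(valid)
        super().__init__(
            f"unknown registry key {name!r}; valid keys: {', '.join(valid)}"
        )

    def __str__(self) -> str:  # KeyError quotes args; keep the message readable
        return self.args[0]


class ConfigError(DqekitError, ValueError):
    """Invalid simulator or pipeline configuration."""


class GeometryError(DqekitError, ValueError):
    """ROI outside the frame, degenerate extents, or incompatible shapes."""


class LayoutError(DqekitError, ValueError):
    """Invalid phantom layout (disc outside frame, overlapping ROI pair)."""


class EdgeNotFoundError(DqekitError):
    """No usable edge transition located in the ROI."""


class InsufficientDataError(DqekitError):
    """Not enough pixels / bins / ROIs to run the estimator."""


class NormalizationError(DqekitError, ZeroDivisionError):
    """A required normalizer (mean signal, LSF area) is zero."""


class FormatError(DqekitError, ValueError):
    """File content inconsistent with the declared format/geometry."""


class PipelineStageError(DqekitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
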