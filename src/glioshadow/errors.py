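"""Exception hierarchy for glioshadow."""


class GlioshadowError(Exception):
    """Base class for all package errors."""


class LabeledInputError(GlioshadowError):
    """A labeled tissue raster contains a label with no class mapping."""


class RasterFormatError(GlioshadowError):
    """A raster file is malformed (non-rectangular, bad header, ...)."""


class DomainError(GlioshadowError):
    """A spatial domain is too small or otherwise unusable."""


class NumericalBlowupError(GlioshadowError):
    """Non-finite values appeared during time integration."""

    def __init__(self, t_days: float, message: str | None = None):
        self.t_days = t_days
        super().__init__(message or f"non-finite state at t = {t_days:g} days")


class ConditioningError(GlioshadowError):
    """A matrix required by the filter is numerically singular."""


class FilterError(GlioshadowError):
    """A local analysis failed; carries the voxel coordinates."""

    def __init__(self, voxel, message: str | None = None):
        self.voxel = tuple(voxel)
        super().__init__(message or f"local analysis failed at voxel {tuple(voxel)}")
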