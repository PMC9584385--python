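"""Exception hierarchy.

Every error raised on a domain precondition derives from :class:`FractalradError`,
so callers (notably the batch pipeline) can distinguish subject-level analysis
failures from programming errors.
"""


class FractalradError(Exception):
    """Base class for all package-domain errors."""


class MaskFormatError(FractalradError):
    """File could not be read as a scalar NIfTI volume."""


class MaskDimensionError(MaskFormatError):
    """Volume is not 3D (or 3D-collapsible, e.g. a trailing singleton axis)."""


class EmptyMaskError(FractalradError):
    """A mask with no foreground voxels was passed to feature extraction."""


class ParameterError(FractalradError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientScalesError(FractalradError):
    """Fewer than two usable box sizes remain after size skipping."""


class UndefinedLacunarityError(FractalradError):
    """No box size contributes to the lacunarity average."""


class DegenerateDataError(FractalradError):
    """Statistical input carries no usable variation (constant groups, zero margin)."""


class UndefinedAgreementError(FractalradError):
    """Agreement statistic undefined (chance agreement 1, or zero subject variance)."""


class IntegrityError(FractalradError):
    """Tabular output would violate a uniqueness/consistency contract."""


class FitError(FractalradError):
    """Model fitting failed for a reason other than detected separation."""


class ConfigError(FractalradError):
    """A run/simulation configuration file violates its schema."""
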