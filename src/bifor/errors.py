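"""Exception hierarchy.

Every error the pipeline raises deliberately derives from :class:`BiforError`,
so callers can distinguish "this nucleus is unusable" (exclusion) from
programming errors.
"""


class BiforError(Exception):
    """Base class for all package errors."""


class InvalidSceneSpec(BiforError, ValueError):
    """A synthetic scene specification violates its geometric or physical invariants."""


class ChannelMismatchError(BiforError, ValueError):
    """A stack's channel count or channel-role declaration is inconsistent."""


class ManifestError(BiforError, ValueError):
    """A dataset manifest fails validation (duplicate ids, broken replicate range, ...)."""


class NoNucleusFound(BiforError):
    """DAPI segmentation produced no usable nucleus; the scene is excluded."""


class NoLocusFound(BiforError):
    """No locus focus above threshold in the red channel; the nucleus is excluded."""


class NucleusTouchesBorder(BiforError):
    """The segmented nucleus touches the image border; maxima may be truncated."""


class DegenerateSignal(BiforError):
    """The signal channel is identically zero over the nucleus; no ratio is defined."""


class ConfigError(BiforError, ValueError):
    """A run configuration is invalid (unknown key, out-of-range parameter)."""


class PipelineError(BiforError):
    """A whole pipeline stage failed fatally."""
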