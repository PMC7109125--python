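"""Exception hierarchy shared across the toolkit."""


class CanalSegError(Exception):
    """Base class for all canalseg errors."""


class FormatError(CanalSegError):
    """An input file or image does not satisfy the expected format."""


class DegenerateInputError(CanalSegError):
    """Input is too degenerate for the requested operation (e.g. too few
    distinct intensities for multi-level thresholding)."""


class GenerationError(CanalSegError):
    """A synthetic phantom configuration produced an invalid geometry."""


class NoBoneDetectedError(CanalSegError):
    """The ROI pipeline found no voxels above the bone threshold."""


class NoTeethDetectedError(CanalSegError):
    """The ROI pipeline found no tooth object; supply manual thresholds."""
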