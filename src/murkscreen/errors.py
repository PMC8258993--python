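"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataFormatError -> 3,
StageError -> 4.
"""


class MurkscreenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MurkscreenError, ValueError):
    """A numeric argument violates its stated domain (rate <= 0, t outside [0,1], ...)."""


class ConfigError(MurkscreenError, ValueError):
    """A configuration object or file failed validation."""


class DataFormatError(MurkscreenError, ValueError):
    """An on-disk dataset is malformed or internally inconsistent."""


class EmptyPanelError(MurkscreenError, ValueError):
    """A filtering step removed every gene."""


class StageError(MurkscreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
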