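"""Exception hierarchy shared across the toolchain."""


class ContourPoseError(Exception):
    """Base class for all package errors."""


class InputError(ContourPoseError):
    """Unreadable, empty, or otherwise unusable input data."""


class FormatError(ContourPoseError):
    """Structurally inconsistent data (e.g. mixed frame sizes)."""


class ConfigurationError(ContourPoseError):
    """Invalid user-supplied parameter."""


class ContractError(ContourPoseError):
    """A function precondition was violated by the caller."""
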