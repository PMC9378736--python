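"""Exception hierarchy shared across the pipeline."""


class CircScreenError(Exception):
    """Base class for all circscreen errors."""


class ParameterError(CircScreenError, ValueError):
    """An argument is outside its documented range."""


class CapacityError(CircScreenError):
    """The genome cannot host the requested gene layout."""


class ConfigError(CircScreenError, ValueError):
    """A screen configuration is malformed; message carries the key path."""


class FormatError(CircScreenError):
    """An input file violates its format contract (names file and record)."""


class StageError(CircScreenError):
    """A pipeline stage failed or its required input is missing."""
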