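"""Exception types shared across the package."""


class IHCFlowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IHCFlowError):
    """An input configuration violates its invariants."""


class DegenerateInputError(IHCFlowError):
    """Data are valid in form but carry no usable signal (e.g. zero variance)."""


class UndefinedFieldError(IHCFlowError):
    """A field image contains no cell area, so the staining ratio is undefined."""
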