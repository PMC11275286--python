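"""Exception hierarchy shared across the pipeline."""


class VaefusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VaefusionError):
    """A config value or input schema is invalid (e.g. a missing column)."""


class ContractError(VaefusionError):
    """A call violated an interface contract (shape/dim mismatch, bad domain)."""


class DegenerateInputError(VaefusionError):
    """Input is structurally valid but too degenerate to operate on."""
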