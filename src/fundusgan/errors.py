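"""Exception types shared across the package."""


class FundusGANError(Exception):
    """Base class for package errors."""


class InvalidParameterError(FundusGANError, ValueError):
    """A parameter value violates its documented constraints."""


class ConfigurationError(FundusGANError, ValueError):
    """Mutually inconsistent configuration detected before any work is done."""
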