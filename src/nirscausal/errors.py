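"""Exception hierarchy shared across the package."""


class NirscausalError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(NirscausalError, ValueError):
    """Invalid channel registry: missing/duplicate ids, id out of range."""


class SelfLoopError(RegistryError):
    """An ordered channel pair with identical endpoints was requested."""


class ConfigurationError(NirscausalError, ValueError):
    """Invalid simulation or analysis configuration."""


class DegenerateInputError(NirscausalError, ValueError):
    """Input data are degenerate for the requested operation (e.g. a constant
    series handed to an autoregressive fit)."""


class PreconditionError(NirscausalError, ValueError):
    """A documented operation precondition does not hold."""
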