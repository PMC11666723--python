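"""Exception types shared across pipeline stages."""


class UAPipeError(Exception):
    """Base class for all package-specific errors."""


class ConstraintError(UAPipeError):
    """A design/balance invariant cannot be satisfied; message names it."""


class ConfigurationError(UAPipeError):
    """A configuration block is missing or inconsistent."""


class DependencyError(UAPipeError):
    """A pipeline stage requires an upstream artifact that is absent."""


class FitError(UAPipeError):
    """A model fit failed in a way that cannot be flagged on the result."""
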