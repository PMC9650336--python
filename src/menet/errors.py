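"""Exception hierarchy shared across the package."""


class MenetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MenetError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(MenetError, ValueError):
    """A configuration object or file violates its invariants."""


class DegenerateTestError(MenetError, ValueError):
    """A statistical test is undefined for the given samples."""
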