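"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: config/contract errors -> 2,
numerical failures -> 3, I/O failures -> 4.
"""


class HasimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HasimError, ValueError):
    """A physically or numerically invalid parameter value."""


class GeometryError(HasimError, ValueError):
    """Inconsistent geometric setup (grid too small, shift out of range, ...)."""


class ContractError(HasimError, ValueError):
    """Mismatched shapes, grids or element counts between cooperating objects."""


class RangeError(HasimError, ValueError):
    """A requested location lies outside a stored region."""


class NumericalError(HasimError, RuntimeError):
    """NaN/Inf or other numerical breakdown detected during a solve."""


class ConfigError(HasimError, ValueError):
    """Invalid or missing run-configuration key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")
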