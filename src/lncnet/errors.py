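"""Exception hierarchy shared across the package."""


class LncnetError(Exception):
    """Base class for all errors raised by lncnet."""


class ParseError(LncnetError, ValueError):
    """Malformed external input (TSV/BED/GMT/SIF/clinical table)."""


class ConfigError(LncnetError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class PairingError(LncnetError, ValueError):
    """Sample design violates the one-tumor/one-non-tumor-per-patient pairing."""


class UndefinedCorrelationError(LncnetError, ArithmeticError):
    """Correlation requested for a constant vector."""
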