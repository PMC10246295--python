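"""Exception hierarchy shared across the package."""


class BurdenArchError(Exception):
    """Base class for package errors."""


class ConfigurationError(BurdenArchError, ValueError):
    """Invalid configuration values or combinations."""


class AscertainmentError(ConfigurationError):
    """Case ascertainment infeasible at the configured prevalence."""


class DataFormatError(BurdenArchError, ValueError):
    """Malformed input file; message names file, line and column."""
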