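"""Exception hierarchy for ampero."""


class AmperoError(Exception):
    """Base class for all ampero errors."""


class ParameterError(AmperoError, ValueError):
    """An operation was called with an invalid parameter value."""


class ConfigError(AmperoError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(AmperoError, ValueError):
    """A file could not be parsed; the message names the offending field or row."""
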