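"""Exception hierarchy.

All user-facing failures derive from :class:`ScrScoreError` so the CLI can
map them to a single exit code (2) with a readable message.
"""


class ScrScoreError(Exception):
    """Base class for all scrscore errors."""


class ConfigurationError(ScrScoreError):
    """A channel mapping, parameter, or config file is wrong or incomplete."""


class ValidationError(ScrScoreError):
    """Input data violate a documented invariant."""


class ParseError(ScrScoreError):
    """A file could not be parsed; carries row/column context where known."""
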