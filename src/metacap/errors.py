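"""Exception hierarchy.

Two failure classes are distinguished so that callers (and the CLI exit
codes) can separate malformed input files from violated analysis
preconditions.
"""


class MetacapError(Exception):
    """Base class for all package errors."""


class FormatError(MetacapError):
    """An input file violates its on-disk format contract (CLI exit code 2)."""


class ContractError(MetacapError):
    """A validated precondition of an operation is violated (CLI exit code 3)."""
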