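"""Exception hierarchy.

Exit-code mapping in the CLI: user errors (bad input files, bad
parameters) exit 1, anything else exits 2.
"""


class MircoregError(Exception):
    """Base class for all package errors."""


class FormatError(MircoregError, ValueError):
    """An input file does not conform to the expected dialect."""


class ParameterError(MircoregError, ValueError):
    """An operation was called with invalid or infeasible parameters."""
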