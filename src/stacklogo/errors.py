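"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`StackLogoError`, so callers (and the CLI) can separate data problems
from programming errors.
"""


class StackLogoError(Exception):
    """Base class for all errors raised by stacklogo."""


class AlignmentError(StackLogoError):
    """Malformed multiple sequence alignment input."""


class AlphabetError(StackLogoError):
    """Characters or declared alphabet inconsistent with expectations."""


class EmptyInputError(StackLogoError):
    """Input contained no usable sequences/columns/states."""


class HMMFormatError(StackLogoError):
    """Malformed or truncated HMMER3 profile file."""


class PriorError(StackLogoError):
    """Invalid Dirichlet prior specification."""


class LogoError(StackLogoError):
    """Invalid request while assembling or rendering a logo."""
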