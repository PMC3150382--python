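"""Exception hierarchy.

``ValidationError`` covers every user-input problem (malformed matrices,
unknown leaf ids, inconsistent files); the CLI maps it to exit status 2.
Anything else that escapes is an internal error (exit status 1).
"""


class HcsymError(Exception):
    """Base class for all package errors."""


class ValidationError(HcsymError):
    """Invalid user input: bad matrix, unknown id, inconsistent files."""


class NewickParseError(ValidationError):
    """Malformed Newick text; message carries the parser's position info."""
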