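"""Exception hierarchy shared by all modules.

``FormatError`` carries an optional source name and line number so CLI
messages can point at the offending input line; the CLI maps it to exit
code 2 and ``UsageError`` to exit code 1.
"""

from __future__ import annotations


class WgaError(Exception):
    """Base class for all toolkit errors."""


class FormatError(WgaError):
    """Malformed input data (bad CIGAR, inconsistent MAF row, ...)."""

    def __init__(self, message: str, source: str | None = None, line: int | None = None):
        self.source = source
        self.line = line
        prefix = ""
        if source is not None:
            prefix += f"{source}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class UsageError(WgaError):
    """Invalid parameters supplied by the caller."""


class MissingCigarError(WgaError):
    """A PAF record without a cg:Z: tag was asked for base-level detail."""
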