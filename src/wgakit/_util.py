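"""Small shared helpers: stream opening with gzip sniffing, reverse complement."""

from __future__ import annotations

import gzip
import io
import sys
from typing import IO, Iterator

GZIP_MAGIC = b"\x1f\x8b"

_RC_TABLE = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string; gaps ('-') are preserved."""
    return seq.translate(_RC_TABLE)[::-1]


def ungapped(text: str) -> str:
    return text.replace("-", "")


def open_text_input(source: str | IO) -> IO[str]:
    """Open ``source`` for text reading.

    Accepts a path, '-' for stdin, or an already-open stream. Gzip input is
    detected by magic bytes, never by file extension.
    """
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if source == "-":
        return sys.stdin
    raw = open(source, "rb")
    if raw.peek(2)[:2] == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))  # type: ignore[arg-type]
    return io.TextIOWrapper(raw)


def open_text_output(dest: str | IO) -> IO[str]:
    if hasattr(dest, "write"):
        return dest  # type: ignore[return-value]
    if dest == "-":
        return sys.stdout
    return open(dest, "w")


def maybe_close(stream: IO, source) -> None:
    """Close ``stream`` only if this module opened it (i.e. source was a path)."""
    if not hasattr(source, "read") and not hasattr(source, "write") and source != "-":
        stream.close()


def numbered_lines(stream: IO[str]) -> Iterator[tuple[int, str]]:
    for lineno, line in enumerate(stream, 1):
        yield lineno, line.rstrip("\n")
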