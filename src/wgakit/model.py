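"""Canonical, format-independent model of a pairwise whole-genome alignment.

Every converter in the package goes through :class:`AlignmentRecord`, which
stores both sides of one alignment in 0-based half-open coordinates on the
forward strand together with a normalized :class:`Cigar`. Strand-relative
coordinate dialects (MAF minus-strand starts, Chain minus-strand query
intervals) exist only at the format boundaries.

The CIGAR alphabet is the extended one: ``=`` match, ``X`` mismatch, ``M``
ambiguous aligned column, ``I`` insertion (consumes query only) and ``D``
deletion (consumes target only) — the PAF/minimap2 reading of I and D.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from ._util import ungapped
from .errors import FormatError, UsageError

CIGAR_KINDS = "=XMID"
QUERY_CONSUMING = frozenset("=XMI")
TARGET_CONSUMING = frozenset("=XMD")
ALIGNED_KINDS = frozenset("=XM")

_CIGAR_RE = re.compile(r"(\d+)([=XMID])")
_VALID_COLUMN_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class CigarOp:
    """One run-length operation of a CIGAR string."""

    kind: str
    length: int

    def __post_init__(self) -> None:
        if self.kind not in CIGAR_KINDS:
            raise FormatError(f"illegal CIGAR operation {self.kind!r} (expected one of {CIGAR_KINDS})")
        if self.length < 1:
            raise FormatError(f"CIGAR operation length must be >= 1, got {self.length}")

    def __str__(self) -> str:
        return f"{self.length}{self.kind}"


class Cigar:
    """Normalized run-length CIGAR: no two consecutive ops share a kind.

    Construction merges adjacent ops of equal kind, so any op sequence
    yields the canonical form.
    """

    __slots__ = ("ops",)

    def __init__(self, ops: Iterable[CigarOp] = ()):
        merged: list[CigarOp] = []
        for op in ops:
            if merged and merged[-1].kind == op.kind:
                merged[-1] = CigarOp(op.kind, merged[-1].length + op.length)
            else:
                merged.append(op)
        self.ops: tuple[CigarOp, ...] = tuple(merged)

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        if not text:
            raise FormatError("empty CIGAR string")
        pos = 0
        ops = []
        for m in _CIGAR_RE.finditer(text):
            if m.start() != pos:
                raise FormatError(f"malformed CIGAR string near {text[pos:pos + 8]!r}")
            ops.append(CigarOp(m.group(2), int(m.group(1))))
            pos = m.end()
        if pos != len(text):
            raise FormatError(f"malformed CIGAR string near {text[pos:pos + 8]!r}")
        return cls(ops)

    @classmethod
    def from_kinds(cls, kinds: Iterable[str]) -> "Cigar":
        """Build from one kind symbol per alignment column."""
        return cls(CigarOp(k, 1) for k in kinds)

    def to_kinds(self) -> str:
        """Expand to one symbol per alignment column (inverse of from_kinds)."""
        return "".join(op.kind * op.length for op in self.ops)

    def __str__(self) -> str:
        return "".join(str(op) for op in self.ops)

    def __repr__(self) -> str:
        return f"Cigar({self})"

    def __iter__(self) -> Iterator[CigarOp]:
        return iter(self.ops)

    def __len__(self) -> int:
        return len(self.ops)

    def __bool__(self) -> bool:
        return bool(self.ops)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Cigar) and self.ops == other.ops

    def __hash__(self) -> int:
        return hash(self.ops)

    @property
    def query_consumed(self) -> int:
        return sum(op.length for op in self.ops if op.kind in QUERY_CONSUMING)

    @property
    def target_consumed(self) -> int:
        return sum(op.length for op in self.ops if op.kind in TARGET_CONSUMING)

    @property
    def columns(self) -> int:
        return sum(op.length for op in self.ops)

    def stats(self) -> "CigarStats":
        matches = mismatches = ambiguous = 0
        ins_events = ins_bases = del_events = del_bases = 0
        for op in self.ops:
            if op.kind == "=":
                matches += op.length
            elif op.kind == "X":
                mismatches += op.length
            elif op.kind == "M":
                ambiguous += op.length
            elif op.kind == "I":
                ins_events += 1
                ins_bases += op.length
            elif op.kind == "D":
                del_events += 1
                del_bases += op.length
        return CigarStats(
            matches=matches,
            mismatches=mismatches,
            ambiguous=ambiguous,
            insertion_events=ins_events,
            insertion_bases=ins_bases,
            deletion_events=del_events,
            deletion_bases=del_bases,
            columns=self.columns,
        )


@dataclass(frozen=True)
class CigarStats:
    """Per-kind counts over one CIGAR; columns = sum of all run lengths."""

    matches: int
    mismatches: int
    ambiguous: int
    insertion_events: int
    insertion_bases: int
    deletion_events: int
    deletion_bases: int
    columns: int

    @property
    def aligned_columns(self) -> int:
        """Columns where both sequences contribute a base."""
        return self.matches + self.mismatches + self.ambiguous


def cigar_stats(cigar: Cigar) -> CigarStats:
    return cigar.stats()


def classify_column(t: str, q: str, index: int | None = None) -> str:
    """Map one alignment column (target char, query char) to a CIGAR kind.

    Comparison is case-insensitive; 'N' against anything (including 'N')
    classifies as a mismatch. A column gapped on both sides is malformed.
    """
    tu, qu = t.upper(), q.upper()
    where = "" if index is None else f"column {index}: "
    for base in (tu, qu):
        if base not in _VALID_COLUMN_CHARS:
            raise FormatError(f"{where}illegal character {base!r} in aligned text")
    if tu == "-" and qu == "-":
        raise FormatError(f"{where}gap in both rows")
    if tu == "-":
        return "I"
    if qu == "-":
        return "D"
    if tu == "N" or qu == "N":
        return "X"
    return "=" if tu == qu else "X"


def cigar_from_texts(target_text: str, query_text: str) -> Cigar:
    """Derive the CIGAR from two gapped alignment rows by a column walk.

    MAF blocks carry no CIGAR, so every MAF ingest path runs through here.
    'M' never appears in the output: sequence is available, so every aligned
    column resolves to '=' or 'X'.
    """
    if not target_text or not query_text:
        raise FormatError("aligned texts must be non-empty")
    if len(target_text) != len(query_text):
        raise FormatError(
            f"aligned texts differ in length ({len(target_text)} vs {len(query_text)})"
        )
    kinds = [classify_column(t, q, i) for i, (t, q) in enumerate(zip(target_text, query_text))]
    return Cigar.from_kinds(kinds)


def _texts_consistent_with_cigar(target_text: str, query_text: str, cigar: Cigar) -> bool:
    """True iff the column classes of the texts reproduce the cigar.

    An 'M' op in the stored cigar accepts any base-against-base column.
    """
    expanded = cigar.to_kinds()
    if len(expanded) != len(target_text):
        return False
    for i, kind in enumerate(expanded):
        derived = classify_column(target_text[i], query_text[i], i)
        if kind == "M":
            if derived not in ("=", "X"):
                return False
        elif derived != kind:
            return False
    return True


@dataclass
class AlignmentRecord:
    """One pairwise alignment in canonical coordinates.

    ``query_start``/``query_end`` are always on the forward strand of the
    query, regardless of ``strand``. When texts are present, ``query_text``
    is the gapped row in alignment orientation: for a '-' strand record its
    ungapped content is the reverse complement of the forward-strand query
    interval.
    """

    query_name: str
    query_size: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_size: int
    target_start: int
    target_end: int
    cigar: Cigar
    query_text: Optional[str] = None
    target_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.query_text is not None:
            self.query_text = self.query_text.upper()
        if self.target_text is not None:
            self.target_text = self.target_text.upper()
        self.validate()

    def validate(self) -> None:
        for side, start, end, size in (
            ("query", self.query_start, self.query_end, self.query_size),
            ("target", self.target_start, self.target_end, self.target_size),
        ):
            if not (0 <= start <= end <= size):
                raise FormatError(
                    f"{side} interval [{start}, {end}) out of bounds for size {size}"
                )
        qspan = self.query_end - self.query_start
        tspan = self.target_end - self.target_start
        if qspan != self.cigar.query_consumed:
            raise FormatError(
                f"query span {qspan} disagrees with CIGAR query-consumed "
                f"{self.cigar.query_consumed}"
            )
        if tspan != self.cigar.target_consumed:
            raise FormatError(
                f"target span {tspan} disagrees with CIGAR target-consumed "
                f"{self.cigar.target_consumed}"
            )
        if (self.query_text is None) != (self.target_text is None):
            raise FormatError("either both aligned texts or neither must be present")
        if self.query_text is not None and self.target_text is not None:
            if len(self.query_text) != len(self.target_text):
                raise FormatError("aligned texts differ in length")
            if len(ungapped(self.target_text)) != tspan:
                raise FormatError("ungapped target text length disagrees with target interval")
            if len(ungapped(self.query_text)) != qspan:
                raise FormatError("ungapped query text length disagrees with query interval")
            if not _texts_consistent_with_cigar(self.target_text, self.query_text, self.cigar):
                raise FormatError("aligned texts do not reproduce the stored CIGAR")

    @property
    def has_texts(self) -> bool:
        return self.query_text is not None

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def ungapped_query(self) -> str:
        if self.query_text is None:
            raise UsageError("record carries no aligned texts")
        return ungapped(self.query_text)

    def ungapped_target(self) -> str:
        if self.target_text is None:
            raise UsageError("record carries no aligned texts")
        return ungapped(self.target_text)

    def replaced(self, **changes) -> "AlignmentRecord":
        return replace(self, **changes)


_REGION_RE = re.compile(r"^(?P<name>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class Region:
    """Half-open 0-based interval on a named sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_string(cls, text: str, one_based: bool = True) -> "Region":
        """Parse ``chr1:100-200``; by default coordinates are 1-based inclusive."""
        m = _REGION_RE.match(text)
        if not m:
            raise UsageError(f"cannot parse region {text!r} (expected NAME:START-END)")
        start, end = int(m.group("start")), int(m.group("end"))
        if one_based:
            start -= 1
        return cls(m.group("name"), start, end)

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start
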