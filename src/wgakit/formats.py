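"""Readers and writers for MAF, PAF, UCSC Chain, FASTA and VCF.

All readers are streaming generators, accept paths, '-' (stdin) or open
streams, and transparently decompress gzip input detected by magic bytes.
Writers emit a normalized dialect (uppercase MAF text, tab-separated Chain
data lines) chosen so that ``read(write(x)) == x`` and, on files the
writers produced, ``write(read(f)) == f``.

Coordinate dialects, fixed here and nowhere else:

* MAF row starts are strand-relative — a '-' row's start counts from the
  reverse-complemented sequence;
* PAF query intervals are always forward-strand;
* Chain minus-strand query coordinates are reverse-complement-relative.

The identity linking the dialects is ``forward_start = size - (rc_start + span)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional

from Bio import SeqIO

from ._util import (
    maybe_close,
    open_text_input,
    open_text_output,
    reverse_complement,
    ungapped,
)
from .errors import FormatError, UsageError
from .model import Cigar

logger = logging.getLogger("wgakit")


# ---------------------------------------------------------------------------
# MAF


@dataclass
class MafRow:
    """One 's' line: src, strand-relative start, ungapped size, strand, src size, gapped text."""

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"MAF row {self.src}: strand must be '+' or '-'")
        if len(ungapped(self.text)) != self.size:
            raise FormatError(
                f"MAF row {self.src}: ungapped text length {len(ungapped(self.text))} "
                f"disagrees with declared size {self.size}"
            )
        if self.start < 0 or self.start + self.size > self.src_size:
            raise FormatError(
                f"MAF row {self.src}: interval start {self.start} + size {self.size} "
                f"exceeds source size {self.src_size}"
            )

    def forward_interval(self) -> tuple[int, int]:
        """The row's interval on the forward strand of its source sequence."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - (self.start + self.size), self.src_size - self.start


@dataclass
class MafBlock:
    """One alignment block; by convention row 0 is the target/reference."""

    rows: list[MafRow]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("MAF block must have at least 2 rows")
        widths = {len(r.text) for r in self.rows}
        if len(widths) != 1:
            raise FormatError("MAF block rows differ in gapped text length")

    @property
    def target(self) -> MafRow:
        return self.rows[0]

    @property
    def query(self) -> MafRow:
        return self.rows[1]

    @property
    def width(self) -> int:
        return len(self.rows[0].text)


def read_maf(source) -> Iterator[MafBlock]:
    """Yield MAF blocks in file order; blocks with fewer than 2 's' rows are
    skipped with a logged warning."""
    stream = open_text_input(source)
    name = source if isinstance(source, str) else "<stream>"
    try:
        score: Optional[float] = None
        rows: list[MafRow] = []
        in_block = False

        def finish() -> Optional[MafBlock]:
            if not in_block:
                return None
            if len(rows) < 2:
                logger.warning("%s: skipping MAF block with %d row(s)", name, len(rows))
                return None
            return MafBlock(rows=list(rows), score=score)

        for lineno, raw in enumerate(stream, 1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                block = finish()
                if block is not None:
                    yield block
                score, rows, in_block = None, [], False
                continue
            if line.startswith("a"):
                block = finish()
                if block is not None:
                    yield block
                score, rows, in_block = None, [], True
                for token in line.split()[1:]:
                    if token.startswith("score="):
                        try:
                            score = float(token[6:])
                        except ValueError as exc:
                            raise FormatError(f"bad score {token!r}", name, lineno) from exc
            elif line.startswith("s"):
                fields = line.split()
                if len(fields) != 7:
                    raise FormatError(
                        f"MAF 's' line has {len(fields)} fields, expected 7", name, lineno
                    )
                try:
                    row = MafRow(
                        src=fields[1],
                        start=int(fields[2]),
                        size=int(fields[3]),
                        strand=fields[4],
                        src_size=int(fields[5]),
                        text=fields[6],
                    )
                except ValueError as exc:
                    raise FormatError(f"non-integer MAF coordinate: {exc}", name, lineno) from exc
                except FormatError as exc:
                    raise FormatError(str(exc), name, lineno) from exc
                rows.append(row)
            # 'q', 'i', 'e' annotation lines are tolerated and dropped
        block = finish()
        if block is not None:
            yield block
    finally:
        maybe_close(stream, source)


def write_maf(blocks: Iterable[MafBlock], dest) -> None:
    stream = open_text_output(dest)
    try:
        stream.write("##maf version=1\n")
        for block in blocks:
            if block.score is None:
                stream.write("a\n")
            else:
                stream.write(f"a score={block.score:g}\n")
            for row in block.rows:
                stream.write(
                    f"s {row.src} {row.start} {row.size} {row.strand} "
                    f"{row.src_size} {row.text.upper()}\n"
                )
            stream.write("\n")
    finally:
        stream.flush()
        maybe_close(stream, dest)


# ---------------------------------------------------------------------------
# PAF


@dataclass
class PafRecord:
    """The 12 mandatory PAF columns plus optional tags kept verbatim."""

    query_name: str
    query_size: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_size: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"PAF strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_size):
            raise FormatError(
                f"PAF query interval [{self.query_start}, {self.query_end}) "
                f"out of bounds for length {self.query_size}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_size):
            raise FormatError(
                f"PAF target interval [{self.target_start}, {self.target_end}) "
                f"out of bounds for length {self.target_size}"
            )
        if self.residue_matches > self.block_length:
            raise FormatError(
                f"PAF residue matches {self.residue_matches} exceed "
                f"block length {self.block_length}"
            )

    @property
    def cigar(self) -> Optional[Cigar]:
        for tag in self.tags:
            if tag.startswith("cg:Z:"):
                return Cigar.from_string(tag[5:])
        return None

    def to_line(self) -> str:
        fields = [
            self.query_name,
            str(self.query_size),
            str(self.query_start),
            str(self.query_end),
            self.strand,
            self.target_name,
            str(self.target_size),
            str(self.target_start),
            str(self.target_end),
            str(self.residue_matches),
            str(self.block_length),
            str(self.mapping_quality),
        ]
        return "\t".join(fields + list(self.tags))


def read_paf(source) -> Iterator[PafRecord]:
    stream = open_text_input(source)
    name = source if isinstance(source, str) else "<stream>"
    try:
        for lineno, raw in enumerate(stream, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"PAF line has {len(fields)} columns, expected >= 12", name, lineno
                )
            try:
                record = PafRecord(
                    query_name=fields[0],
                    query_size=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_name=fields[5],
                    target_size=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    residue_matches=int(fields[9]),
                    block_length=int(fields[10]),
                    mapping_quality=int(fields[11]),
                    tags=fields[12:],
                )
            except ValueError as exc:
                raise FormatError(f"non-integer PAF coordinate: {exc}", name, lineno) from exc
            except FormatError as exc:
                raise FormatError(str(exc), name, lineno) from exc
            try:
                record.cigar  # validates cg tag syntax eagerly
            except FormatError as exc:
                raise FormatError(str(exc), name, lineno) from exc
            yield record
    finally:
        maybe_close(stream, source)


def write_paf(records: Iterable[PafRecord], dest) -> None:
    stream = open_text_output(dest)
    try:
        for record in records:
            stream.write(record.to_line() + "\n")
    finally:
        stream.flush()
        maybe_close(stream, dest)


# ---------------------------------------------------------------------------
# Chain


@dataclass
class ChainRecord:
    """A UCSC chain: header intervals plus gapless blocks linked by (size, dt, dq).

    ``lines`` holds one (size, dt, dq) triple per data line; the final line
    must have dt == dq == 0 and is written with the bare size, per the chain
    grammar. The target strand is always '+'; minus-strand query coordinates
    count from the reverse-complemented query.
    """

    score: int
    target_name: str
    target_size: int
    target_start: int
    target_end: int
    query_name: str
    query_size: int
    query_strand: str
    query_start: int
    query_end: int
    chain_id: int
    lines: list[tuple[int, int, int]]
    target_strand: str = "+"

    def __post_init__(self) -> None:
        if self.target_strand != "+":
            raise FormatError(f"chain {self.chain_id}: target strand must be '+'")
        if self.query_strand not in ("+", "-"):
            raise FormatError(f"chain {self.chain_id}: bad query strand {self.query_strand!r}")
        if not self.lines:
            raise FormatError(f"chain {self.chain_id}: no data lines")
        if self.lines[-1][1] != 0 or self.lines[-1][2] != 0:
            raise FormatError(f"chain {self.chain_id}: final data line must carry size only")
        for size, dt, dq in self.lines:
            if size < 1:
                raise FormatError(f"chain {self.chain_id}: block size {size} < 1")
            if dt < 0 or dq < 0:
                raise FormatError(f"chain {self.chain_id}: negative gap length")
        sum_size = sum(s for s, _, _ in self.lines)
        sum_dt = sum(dt for _, dt, _ in self.lines)
        sum_dq = sum(dq for _, _, dq in self.lines)
        if sum_size + sum_dt != self.target_end - self.target_start:
            raise FormatError(
                f"chain {self.chain_id}: sum(size) + sum(dt) = {sum_size + sum_dt} "
                f"but target span = {self.target_end - self.target_start}"
            )
        if sum_size + sum_dq != self.query_end - self.query_start:
            raise FormatError(
                f"chain {self.chain_id}: sum(size) + sum(dq) = {sum_size + sum_dq} "
                f"but query span = {self.query_end - self.query_start}"
            )

    def forward_query_interval(self) -> tuple[int, int]:
        if self.query_strand == "+":
            return self.query_start, self.query_end
        return (
            self.query_size - self.query_end,
            self.query_size - self.query_start,
        )


def read_chain(source) -> Iterator[ChainRecord]:
    stream = open_text_input(source)
    name = source if isinstance(source, str) else "<stream>"
    try:
        header: Optional[list[str]] = None
        header_line = 0
        lines: list[tuple[int, int, int]] = []
        closed = False

        def finish(lineno: int) -> ChainRecord:
            assert header is not None
            if not closed:
                raise FormatError(
                    "chain record not terminated by a size-only data line", name, lineno
                )
            try:
                return ChainRecord(
                    score=int(header[1]),
                    target_name=header[2],
                    target_size=int(header[3]),
                    target_strand=header[4],
                    target_start=int(header[5]),
                    target_end=int(header[6]),
                    query_name=header[7],
                    query_size=int(header[8]),
                    query_strand=header[9],
                    query_start=int(header[10]),
                    query_end=int(header[11]),
                    chain_id=int(header[12]),
                    lines=list(lines),
                )
            except ValueError as exc:
                raise FormatError(f"non-integer chain header field: {exc}", name, header_line) from exc
            except FormatError as exc:
                raise FormatError(str(exc), name, header_line) from exc

        for lineno, raw in enumerate(stream, 1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                if header is not None:
                    yield finish(lineno)
                    header, lines, closed = None, [], False
                continue
            fields = line.split()
            if fields[0] == "chain":
                if header is not None:
                    yield finish(lineno)
                    lines, closed = [], False
                if len(fields) != 13:
                    raise FormatError(
                        f"chain header has {len(fields)} fields, expected 13", name, lineno
                    )
                header, header_line = fields, lineno
            else:
                if header is None:
                    raise FormatError("chain data line before any header", name, lineno)
                if closed:
                    raise FormatError("data line after the final size-only line", name, lineno)
                try:
                    numbers = [int(f) for f in fields]
                except ValueError as exc:
                    raise FormatError(f"non-integer chain data field: {exc}", name, lineno) from exc
                if len(numbers) == 3:
                    lines.append((numbers[0], numbers[1], numbers[2]))
                elif len(numbers) == 1:
                    lines.append((numbers[0], 0, 0))
                    closed = True
                else:
                    raise FormatError(
                        f"chain data line has {len(numbers)} fields, expected 3 or 1",
                        name,
                        lineno,
                    )
        if header is not None:
            yield finish(header_line)
    finally:
        maybe_close(stream, source)


def write_chain(records: Iterable[ChainRecord], dest) -> None:
    stream = open_text_output(dest)
    try:
        for record in records:
            stream.write(
                f"chain {record.score} {record.target_name} {record.target_size} "
                f"{record.target_strand} {record.target_start} {record.target_end} "
                f"{record.query_name} {record.query_size} {record.query_strand} "
                f"{record.query_start} {record.query_end} {record.chain_id}\n"
            )
            for size, dt, dq in record.lines[:-1]:
                stream.write(f"{size}\t{dt}\t{dq}\n")
            stream.write(f"{record.lines[-1][0]}\n")
            stream.write("\n")
    finally:
        stream.flush()
        maybe_close(stream, dest)


# ---------------------------------------------------------------------------
# FASTA access


class SequenceStore:
    """In-memory name -> sequence mapping with strand-aware interval fetch."""

    def __init__(self, sequences: Optional[Mapping[str, str]] = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    @classmethod
    def from_fasta(cls, *paths: str) -> "SequenceStore":
        store = cls()
        for path in paths:
            stream = open_text_input(path)
            try:
                for rec in SeqIO.parse(stream, "fasta"):
                    store.add(rec.id, str(rec.seq))
            finally:
                maybe_close(stream, path)
        return store

    def add(self, name: str, seq: str) -> None:
        self._seqs[name] = seq.upper()

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        if name not in self._seqs:
            raise FormatError(f"sequence {name!r} not found in FASTA store")
        return len(self._seqs[name])

    def fetch(self, name: str, start: int, end: int, strand: str = "+") -> str:
        """Return [start, end) of ``name``; reverse-complemented for strand '-'."""
        if name not in self._seqs:
            raise FormatError(f"sequence {name!r} not found in FASTA store")
        seq = self._seqs[name]
        if not (0 <= start <= end <= len(seq)):
            raise FormatError(
                f"interval [{start}, {end}) out of bounds for sequence "
                f"{name!r} of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


def write_fasta(sequences: Mapping[str, str], dest, width: int = 60) -> None:
    stream = open_text_output(dest)
    try:
        for name, seq in sequences.items():
            stream.write(f">{name}\n")
            for i in range(0, len(seq), width):
                stream.write(seq[i : i + width] + "\n")
    finally:
        stream.flush()
        maybe_close(stream, dest)


# ---------------------------------------------------------------------------
# VCF


VCF_INFO_DEFS = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
    '"Difference in length between ALT and REF alleles">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=QNAME,Number=1,Type=String,Description="Query sequence name">',
    '##INFO=<ID=QSTART,Number=1,Type=Integer,Description='
    '"Query start of the source alignment (0-based)">',
]


def write_vcf(records, contigs: Mapping[str, int], dest, provenance: bool = False) -> None:
    """Write VCF v4.2. ``records`` must be sorted by (contig, position) and
    provide ``contig``, ``pos`` (1-based), ``ref``, ``alt`` and an
    ``info_string(provenance)`` method (see :class:`wgakit.variants.VcfRecord`)."""
    previous = None
    stream = open_text_output(dest)
    try:
        stream.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            stream.write(f"##contig=<ID={name},length={length}>\n")
        for line in VCF_INFO_DEFS:
            stream.write(line + "\n")
        stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for record in records:
            key = (record.contig, record.pos)
            if previous is not None and key < previous:
                raise UsageError(
                    f"VCF records not sorted: {key} after {previous}; sort before writing"
                )
            previous = key
            stream.write(
                f"{record.contig}\t{record.pos}\t.\t{record.ref}\t{record.alt}"
                f"\t.\tPASS\t{record.info_string(provenance)}\n"
            )
    finally:
        stream.flush()
        maybe_close(stream, dest)
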