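"""Lossless conversion among MAF, PAF and Chain through AlignmentRecord.

Every ordered pair of formats composes two of the spoke functions below;
nothing converts format-to-format directly. Conversions that must emit
sequence text (anything -> MAF) reconstruct it from a FASTA-backed
:class:`~wgakit.formats.SequenceStore` when the record carries none.

Chains cannot represent insertions or deletions at the alignment edges, so
edge I/D runs are folded into the interval endpoints before emission; the
same trimming is applied on every export path so the three formats stay
mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .errors import FormatError, MissingCigarError
from .formats import ChainRecord, MafBlock, MafRow, PafRecord, SequenceStore
from .model import (
    ALIGNED_KINDS,
    AlignmentRecord,
    Cigar,
    CigarOp,
    cigar_from_texts,
)
from ._util import reverse_complement

logger = logging.getLogger("wgakit")


# ---------------------------------------------------------------------------
# helpers


def build_texts(cigar: Cigar, target_seq: str, query_seq: str) -> tuple[str, str]:
    """Expand ungapped sequences into gapped alignment rows along a CIGAR."""
    ti = qi = 0
    t_parts: list[str] = []
    q_parts: list[str] = []
    for op in cigar:
        if op.kind in ALIGNED_KINDS:
            t_parts.append(target_seq[ti : ti + op.length])
            q_parts.append(query_seq[qi : qi + op.length])
            ti += op.length
            qi += op.length
        elif op.kind == "I":
            t_parts.append("-" * op.length)
            q_parts.append(query_seq[qi : qi + op.length])
            qi += op.length
        else:  # 'D'
            t_parts.append(target_seq[ti : ti + op.length])
            q_parts.append("-" * op.length)
            ti += op.length
    if ti != len(target_seq) or qi != len(query_seq):
        raise FormatError(
            f"CIGAR consumes ({ti}, {qi}) bases but sequences have "
            f"({len(target_seq)}, {len(query_seq)})"
        )
    return "".join(t_parts), "".join(q_parts)


@dataclass(frozen=True)
class EdgeTrim:
    """Bases removed from the alignment edges because Chain (and our
    normalized MAF/PAF output) cannot represent edge indels."""

    leading_query: int = 0
    leading_target: int = 0
    trailing_query: int = 0
    trailing_target: int = 0

    @property
    def any(self) -> bool:
        return bool(
            self.leading_query
            or self.leading_target
            or self.trailing_query
            or self.trailing_target
        )


def trim_edge_indels(record: AlignmentRecord) -> tuple[AlignmentRecord, EdgeTrim]:
    """Fold leading/trailing I/D runs into the interval endpoints.

    Returns the (possibly identical) record and a tally of trimmed bases.
    """
    ops = list(record.cigar)
    lead_q = lead_t = trail_q = trail_t = 0
    lead_cols = trail_cols = 0
    while ops and ops[0].kind in "ID":
        op = ops.pop(0)
        lead_cols += op.length
        if op.kind == "I":
            lead_q += op.length
        else:
            lead_t += op.length
    while ops and ops[-1].kind in "ID":
        op = ops.pop()
        trail_cols += op.length
        if op.kind == "I":
            trail_q += op.length
        else:
            trail_t += op.length
    trim = EdgeTrim(lead_q, lead_t, trail_q, trail_t)
    if not trim.any:
        return record, trim
    if not ops:
        raise FormatError("alignment consists solely of indels; nothing to emit")
    logger.info(
        "trimmed edge indels from %s vs %s: %s",
        record.query_name,
        record.target_name,
        trim,
    )
    # the CIGAR walks the query in alignment orientation, so on '-' strand
    # records leading query bases come off the forward-strand *end*
    if record.strand == "+":
        q_start = record.query_start + lead_q
        q_end = record.query_end - trail_q
    else:
        q_start = record.query_start + trail_q
        q_end = record.query_end - lead_q
    changes = dict(
        cigar=Cigar(ops),
        query_start=q_start,
        query_end=q_end,
        target_start=record.target_start + lead_t,
        target_end=record.target_end - trail_t,
    )
    if record.has_texts:
        width = record.cigar.columns
        changes["target_text"] = record.target_text[lead_cols : width - trail_cols]
        changes["query_text"] = record.query_text[lead_cols : width - trail_cols]
    return record.replaced(**changes), trim


def _flip_maf_block(block: MafBlock) -> MafBlock:
    """Reverse-complement a block so the target row is on '+'."""
    flipped = []
    for row in block.rows:
        flipped.append(
            MafRow(
                src=row.src,
                start=row.src_size - (row.start + row.size),
                size=row.size,
                strand="-" if row.strand == "+" else "+",
                src_size=row.src_size,
                text=reverse_complement(row.text),
            )
        )
    return MafBlock(rows=flipped, score=block.score)


# ---------------------------------------------------------------------------
# spokes


def maf_to_alignment(block: MafBlock) -> AlignmentRecord:
    """Canonicalize a pairwise MAF block; the CIGAR is derived by a column walk."""
    if len(block.rows) != 2:
        raise FormatError(
            f"conversion requires a pairwise block, got {len(block.rows)} rows"
        )
    if block.target.strand == "-":
        logger.warning(
            "MAF block with '-' target row (%s): flipping both strands", block.target.src
        )
        block = _flip_maf_block(block)
    t, q = block.target, block.query
    t_start, t_end = t.forward_interval()
    q_start, q_end = q.forward_interval()
    cigar = cigar_from_texts(t.text, q.text)
    return AlignmentRecord(
        query_name=q.src,
        query_size=q.src_size,
        query_start=q_start,
        query_end=q_end,
        strand=q.strand,
        target_name=t.src,
        target_size=t.src_size,
        target_start=t_start,
        target_end=t_end,
        cigar=cigar,
        query_text=q.text,
        target_text=t.text,
    )


def alignment_to_maf(
    record: AlignmentRecord,
    store: Optional[SequenceStore] = None,
    score: Optional[float] = None,
) -> MafBlock:
    """Emit a 2-row block, target row first, strand-relative query start."""
    record, _ = trim_edge_indels(record)
    if not record.has_texts:
        if store is None:
            raise FormatError(
                "sequence required: record carries no aligned texts and no FASTA store given"
            )
        record = attach_texts(record, store)
    if record.strand == "+":
        q_maf_start = record.query_start
    else:
        q_maf_start = record.query_size - record.query_end
    rows = [
        MafRow(
            src=record.target_name,
            start=record.target_start,
            size=record.target_span,
            strand="+",
            src_size=record.target_size,
            text=record.target_text,
        ),
        MafRow(
            src=record.query_name,
            start=q_maf_start,
            size=record.query_span,
            strand=record.strand,
            src_size=record.query_size,
            text=record.query_text,
        ),
    ]
    return MafBlock(rows=rows, score=score)


def alignment_to_paf(record: AlignmentRecord) -> PafRecord:
    """Twelve mandatory columns plus the cg:Z: tag.

    Residue matches count '=' bases; unresolved 'M' bases are included
    because the format cannot distinguish them without sequence.
    """
    record, _ = trim_edge_indels(record)
    st = record.cigar.stats()
    return PafRecord(
        query_name=record.query_name,
        query_size=record.query_size,
        query_start=record.query_start,
        query_end=record.query_end,
        strand=record.strand,
        target_name=record.target_name,
        target_size=record.target_size,
        target_start=record.target_start,
        target_end=record.target_end,
        residue_matches=st.matches + st.ambiguous,
        block_length=st.columns,
        mapping_quality=255,
        tags=[f"cg:Z:{record.cigar}"],
    )


def attach_texts(record: AlignmentRecord, store: SequenceStore) -> AlignmentRecord:
    """Reconstruct gapped texts from FASTA and resolve any 'M' ops to '='/'X'."""
    target_seq = store.fetch(record.target_name, record.target_start, record.target_end)
    query_seq = store.fetch(
        record.query_name, record.query_start, record.query_end, record.strand
    )
    t_text, q_text = build_texts(record.cigar, target_seq, query_seq)
    resolved = cigar_from_texts(t_text, q_text)
    return record.replaced(cigar=resolved, target_text=t_text, query_text=q_text)


def paf_to_alignment(
    record: PafRecord, store: Optional[SequenceStore] = None
) -> AlignmentRecord:
    cigar = record.cigar
    if cigar is None:
        raise MissingCigarError(
            f"PAF record {record.query_name} vs {record.target_name} has no cg:Z: tag"
        )
    if cigar.query_consumed != record.query_end - record.query_start:
        raise FormatError(
            f"cg tag consumes {cigar.query_consumed} query bases but the "
            f"query interval spans {record.query_end - record.query_start}"
        )
    if cigar.target_consumed != record.target_end - record.target_start:
        raise FormatError(
            f"cg tag consumes {cigar.target_consumed} target bases but the "
            f"target interval spans {record.target_end - record.target_start}"
        )
    aligned = AlignmentRecord(
        query_name=record.query_name,
        query_size=record.query_size,
        query_start=record.query_start,
        query_end=record.query_end,
        strand=record.strand,
        target_name=record.target_name,
        target_size=record.target_size,
        target_start=record.target_start,
        target_end=record.target_end,
        cigar=cigar,
    )
    if store is not None:
        aligned = attach_texts(aligned, store)
    return aligned


def alignment_to_chain(record: AlignmentRecord, chain_id: int) -> ChainRecord:
    """Merge aligned runs into gapless blocks linked by (size, dt, dq) gaps.

    'D' runs feed dt (target skipped), 'I' runs feed dq (query skipped);
    adjacent I and D runs share one gap line. The score is the residue-match
    count when the CIGAR distinguishes '=' from 'X', else the aligned-column
    count of an all-'M' CIGAR.
    """
    record, _ = trim_edge_indels(record)
    lines: list[tuple[int, int, int]] = []
    size = dt = dq = 0
    for op in record.cigar:
        if op.kind in ALIGNED_KINDS:
            if dt or dq:
                lines.append((size, dt, dq))
                size, dt, dq = 0, 0, 0
            size += op.length
        elif op.kind == "D":
            dt += op.length
        else:  # 'I'
            dq += op.length
    lines.append((size, 0, 0))
    st = record.cigar.stats()
    score = st.matches if (st.matches + st.mismatches) > 0 else st.ambiguous
    if record.strand == "+":
        q_start, q_end = record.query_start, record.query_end
    else:
        q_start = record.query_size - record.query_end
        q_end = record.query_size - record.query_start
    return ChainRecord(
        score=score,
        target_name=record.target_name,
        target_size=record.target_size,
        target_start=record.target_start,
        target_end=record.target_end,
        query_name=record.query_name,
        query_size=record.query_size,
        query_strand=record.strand,
        query_start=q_start,
        query_end=q_end,
        chain_id=chain_id,
        lines=lines,
    )


def chain_to_alignment(
    record: ChainRecord, store: Optional[SequenceStore] = None
) -> AlignmentRecord:
    """Inverse of :func:`alignment_to_chain` up to 'M' resolution.

    Without sequence, aligned blocks become 'M' runs and each gap line
    expands to 'D' then 'I' (the chain grammar does not order the two gaps
    of one line). With a store, 'M' resolves to '='/'X' from the sequences.
    """
    ops: list[CigarOp] = []
    for size, dt, dq in record.lines:
        ops.append(CigarOp("M", size))
        if dt:
            ops.append(CigarOp("D", dt))
        if dq:
            ops.append(CigarOp("I", dq))
    q_start, q_end = record.forward_query_interval()
    aligned = AlignmentRecord(
        query_name=record.query_name,
        query_size=record.query_size,
        query_start=q_start,
        query_end=q_end,
        strand=record.query_strand,
        target_name=record.target_name,
        target_size=record.target_size,
        target_start=record.target_start,
        target_end=record.target_end,
        cigar=Cigar(ops),
    )
    if store is not None:
        aligned = attach_texts(aligned, store)
    return aligned


# ---------------------------------------------------------------------------
# stream-level conversions used by the CLI


def paf_stream_to_alignments(
    records: Iterable[PafRecord], store: Optional[SequenceStore] = None
) -> Iterator[AlignmentRecord]:
    """Convert a PAF stream, skipping (with a logged count) records lacking cg."""
    skipped = 0
    for record in records:
        try:
            yield paf_to_alignment(record, store)
        except MissingCigarError:
            skipped += 1
    if skipped:
        logger.warning("skipped %d PAF record(s) without a cg:Z: tag", skipped)


def maf_stream_to_alignments(blocks: Iterable[MafBlock]) -> Iterator[AlignmentRecord]:
    for block in blocks:
        yield maf_to_alignment(block)


def alignments_to_chains(records: Iterable[AlignmentRecord]) -> Iterator[ChainRecord]:
    for chain_id, record in enumerate(records, 1):
        yield alignment_to_chain(record, chain_id)
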