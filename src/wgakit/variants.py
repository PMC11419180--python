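"""Variant calling from alignment signatures.

Each CIGAR run in a sequence-bearing record maps directly to variants:

* an ``X`` run of length L emits L SNP records, one per column;
* an ``I`` run emits one insertion, left-anchored on the target base
  immediately before the run (REF = anchor, ALT = anchor + inserted bases);
* a ``D`` run emits one deletion (REF = anchor + deleted bases, ALT = anchor);
* a minus-strand record flanked by plus-strand records of the same query is
  reported as an inversion (symbolic ``<INV>`` allele) — a deliberately
  conservative heuristic.

Runs of length >= ``sv_threshold`` (default 50 bp) carry SVTYPE/SVLEN
annotations. Indel placement follows the input alignment: no left-shifting
or re-normalization is attempted beyond the anchor base.

The calls are self-validating: :func:`apply_variants` replays SNP/INS/DEL
records onto the target subsequence and must reproduce the query
subsequence exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import FormatError, UsageError
from .model import ALIGNED_KINDS, AlignmentRecord, cigar_from_texts

logger = logging.getLogger("wgakit")

SV_THRESHOLD_DEFAULT = 50
CLASSES = ("snp", "ins", "del", "inv")


@dataclass(frozen=True)
class VcfRecord:
    """One called variant; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str
    svtype: Optional[str] = None  # INS/DEL >= threshold, or INV; None for plain calls
    svlen: Optional[int] = None  # signed: +L insertion, -L deletion, +span inversion
    end: Optional[int] = None
    query_name: Optional[str] = None
    query_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("VCF alleles must be non-empty")

    @property
    def variant_class(self) -> str:
        if self.alt == "<INV>":
            return "inv"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "ins" if len(self.alt) > len(self.ref) else "del"

    def sort_key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    def identity(self) -> tuple:
        """The fields that define the call (used for truth-set comparison)."""
        return (self.contig, self.pos, self.ref, self.alt, self.svtype, self.svlen)

    def info_string(self, provenance: bool = False) -> str:
        parts = []
        if self.svtype is not None:
            parts.append(f"SVTYPE={self.svtype}")
        if self.svlen is not None:
            parts.append(f"SVLEN={self.svlen}")
        if self.end is not None:
            parts.append(f"END={self.end}")
        if provenance and self.query_name is not None:
            parts.append(f"QNAME={self.query_name}")
            if self.query_start is not None:
                parts.append(f"QSTART={self.query_start}")
        return ";".join(parts) if parts else "."


def _sv_fields(kind: str, length: int, threshold: int) -> tuple[Optional[str], Optional[int]]:
    if length < threshold:
        return None, None
    if kind == "I":
        return "INS", length
    return "DEL", -length


def call_variants(
    record: AlignmentRecord,
    classes: Sequence[str] = ("snp", "ins", "del"),
    sv_threshold: int = SV_THRESHOLD_DEFAULT,
    min_len: Optional[dict[str, int]] = None,
    tally: Optional[dict[str, int]] = None,
) -> list[VcfRecord]:
    """Call SNPs and indels from one sequence-bearing record.

    ``min_len`` maps a class name to the minimum run length to report
    (SNPs have run length 1 per emitted record). An indel run at the very
    start of the alignment has no left anchor base and is skipped; pass a
    ``tally`` dict to collect such skips under ``"unanchored"``.
    """
    for cls in classes:
        if cls not in CLASSES:
            raise UsageError(f"unknown variant class {cls!r}")
    if not record.has_texts:
        raise UsageError("variant calling needs aligned sequence texts")
    min_len = min_len or {}
    if tally is None:
        tally = {}
    # resolve any 'M' ops so every aligned column is '=' or 'X'
    cigar = cigar_from_texts(record.target_text, record.query_text)
    out: list[VcfRecord] = []
    tpos = record.target_start  # 0-based forward target coordinate of next column
    col = 0
    last_target_base: Optional[str] = None
    for op in cigar:
        t_run = record.target_text[col : col + op.length]
        q_run = record.query_text[col : col + op.length]
        if op.kind in ALIGNED_KINDS:
            if op.kind == "X" and "snp" in classes and op.length >= min_len.get("snp", 1):
                for k in range(op.length):
                    out.append(
                        VcfRecord(
                            contig=record.target_name,
                            pos=tpos + k + 1,
                            ref=t_run[k],
                            alt=q_run[k],
                            query_name=record.query_name,
                            query_start=record.query_start,
                        )
                    )
            tpos += op.length
            last_target_base = t_run[-1]
        elif op.kind == "I":
            if last_target_base is None:
                tally["unanchored"] = tally.get("unanchored", 0) + 1
                logger.warning(
                    "skipping unanchored insertion at alignment start (%s:%d)",
                    record.target_name,
                    tpos,
                )
            elif "ins" in classes and op.length >= min_len.get("ins", 1):
                svtype, svlen = _sv_fields("I", op.length, sv_threshold)
                out.append(
                    VcfRecord(
                        contig=record.target_name,
                        pos=tpos,  # 1-based position of the anchor base (0-based tpos-1)
                        ref=last_target_base,
                        alt=last_target_base + q_run,
                        svtype=svtype,
                        svlen=svlen,
                        query_name=record.query_name,
                        query_start=record.query_start,
                    )
                )
        else:  # 'D'
            if last_target_base is None:
                tally["unanchored"] = tally.get("unanchored", 0) + 1
                logger.warning(
                    "skipping unanchored deletion at alignment start (%s:%d)",
                    record.target_name,
                    tpos,
                )
            elif "del" in classes and op.length >= min_len.get("del", 1):
                svtype, svlen = _sv_fields("D", op.length, sv_threshold)
                out.append(
                    VcfRecord(
                        contig=record.target_name,
                        pos=tpos,
                        ref=last_target_base + t_run,
                        alt=last_target_base,
                        svtype=svtype,
                        svlen=svlen,
                        query_name=record.query_name,
                        query_start=record.query_start,
                    )
                )
            tpos += op.length
            last_target_base = t_run[-1]
        col += op.length
    out.sort(key=VcfRecord.sort_key)
    return out


def call_inversions(records: Iterable[AlignmentRecord]) -> list[VcfRecord]:
    """Flag minus-strand records flanked by plus-strand records of the same
    query/target pair as inversions.

    A lone minus-strand record (no plus-strand neighbour on both sides in
    target coordinates) is not called: without flanking colinear alignment
    there is no evidence the segment is inverted in place.
    """
    grouped: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for record in records:
        grouped.setdefault((record.query_name, record.target_name), []).append(record)
    out: list[VcfRecord] = []
    for (qname, tname), group in sorted(grouped.items()):
        plus = [r for r in group if r.strand == "+"]
        for record in group:
            if record.strand != "-":
                continue
            left = any(p.target_end <= record.target_start for p in plus)
            right = any(p.target_start >= record.target_end for p in plus)
            if not (left and right):
                continue
            ref_base = (
                record.ungapped_target()[0] if record.has_texts else "N"
            )
            span = record.target_span
            out.append(
                VcfRecord(
                    contig=tname,
                    pos=record.target_start + 1,
                    ref=ref_base,
                    alt="<INV>",
                    svtype="INV",
                    svlen=span,
                    end=record.target_end,
                    query_name=qname,
                    query_start=record.query_start,
                )
            )
    out.sort(key=VcfRecord.sort_key)
    return out


def apply_variants(
    target_subseq: str, variants: Sequence[VcfRecord], offset: int = 0
) -> str:
    """Replay SNP/INS/DEL calls onto the target subsequence.

    ``offset`` is the 0-based target coordinate of ``target_subseq[0]``.
    Inversion records are ignored. This is the round-trip oracle for
    :func:`call_variants`: the result must equal the (alignment-oriented)
    query subsequence.
    """
    seq = list(target_subseq)
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if v.variant_class == "inv":
            continue
        i = v.pos - 1 - offset
        if not (0 <= i < len(target_subseq)):
            raise UsageError(f"variant at {v.contig}:{v.pos} outside the subsequence")
        if v.variant_class == "snp":
            if seq[i] != v.ref:
                raise FormatError(
                    f"REF mismatch at {v.contig}:{v.pos}: expected {v.ref}, found {seq[i]}"
                )
            seq[i] = v.alt
        elif v.variant_class == "del":
            removed = "".join(seq[i : i + len(v.ref)])
            if removed != v.ref:
                raise FormatError(
                    f"REF mismatch at {v.contig}:{v.pos}: expected {v.ref}, found {removed}"
                )
            del seq[i + 1 : i + len(v.ref)]
        else:  # ins
            if seq[i] != v.ref:
                raise FormatError(
                    f"REF mismatch at {v.contig}:{v.pos}: expected {v.ref}, found {seq[i]}"
                )
            seq[i + 1 : i + 1] = list(v.alt[1:])
    return "".join(seq)
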