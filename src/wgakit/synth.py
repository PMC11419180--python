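"""Deterministic synthetic genome pairs with planted, known mutations.

The generator draws a uniform-random ACGT reference, plants SNPs,
insertions, deletions and optionally one inverted segment, and emits the
exact alignment its own construction implies (as truth MAF blocks) together
with the matching truth variant records. Every other module is tested
against this substrate: the planted events are the ground truth that
variant calling, conversion round-trips and statistics must reproduce.

Placement uses rejection sampling under the seed. Event footprints (an
indel's anchor base included) must sit strictly inside the reference, at
least 2 bp from each other and from the sequence ends, so no alignment
starts or ends in an indel and every indel has a left anchor base. An
inverted segment is represented as three truth blocks (+, -, +), which is
exactly the signature the inversion caller looks for.

This is deliberately not a mutation-rate model: no transition/transversion
bias, no repeats, no breakpoint microhomology.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from ._util import reverse_complement, ungapped
from .errors import UsageError
from .formats import MafBlock, MafRow, SequenceStore, write_fasta, write_maf, write_vcf
from .variants import SV_THRESHOLD_DEFAULT, VcfRecord

_BASES = "ACGT"
_MIN_EVENT_GAP = 2
_MAX_PLACEMENT_TRIES = 10_000


@dataclass(frozen=True)
class MutationSpec:
    """What to plant: counts/lengths of each event class plus the seed."""

    n_snps: int = 0
    insertions: tuple[int, ...] = ()
    deletions: tuple[int, ...] = ()
    inversion: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise UsageError("n_snps must be >= 0")
        object.__setattr__(self, "insertions", tuple(self.insertions))
        object.__setattr__(self, "deletions", tuple(self.deletions))
        for length in (*self.insertions, *self.deletions):
            if length < 1:
                raise UsageError("indel lengths must be >= 1")
        if self.inversion is not None and self.inversion < 2:
            raise UsageError("inversion length must be >= 2")


@dataclass(frozen=True)
class _Snp:
    pos: int
    alt: str


@dataclass(frozen=True)
class _Ins:
    anchor: int  # inserted between anchor and anchor + 1
    seq: str


@dataclass(frozen=True)
class _Del:
    start: int
    length: int


@dataclass
class GenomePair:
    """Generator output: sequences, truth alignment, truth variants."""

    ref_name: str
    qry_name: str
    ref_seq: str
    qry_seq: str
    blocks: list[MafBlock]
    variants: list[VcfRecord]
    spec: MutationSpec

    def store(self) -> SequenceStore:
        return SequenceStore({self.ref_name: self.ref_seq, self.qry_name: self.qry_seq})

    def alignments(self):
        from .convert import maf_to_alignment

        return [maf_to_alignment(b) for b in self.blocks]


def _place_events(
    ref: str, spec: MutationSpec, rng: random.Random
) -> tuple[list, Optional[tuple[int, int]]]:
    """Choose non-overlapping event positions; returns (events, inversion interval)."""
    length = len(ref)
    footprints: list[tuple[int, int]] = []

    def fits(s: int, e: int) -> bool:
        if s < 1 or e > length - 1:
            return False
        return all(s >= pe + _MIN_EVENT_GAP or e + _MIN_EVENT_GAP <= ps for ps, pe in footprints)

    def place(span: int) -> int:
        if length - 1 - span <= 1:
            raise UsageError(f"reference of {length} bp cannot host a {span} bp event")
        for _ in range(_MAX_PLACEMENT_TRIES):
            s = rng.randrange(1, length - 1 - span + 1)
            if fits(s, s + span):
                footprints.append((s, s + span))
                return s
        raise UsageError(
            f"could not place a {span} bp event after {_MAX_PLACEMENT_TRIES} tries; "
            "too many events for the reference length"
        )

    inversion_interval = None
    if spec.inversion is not None:
        a = place(spec.inversion)
        inversion_interval = (a, a + spec.inversion)

    events: list = []
    for dlen in sorted(spec.deletions, reverse=True):
        # footprint includes the anchor base to the left
        s = place(dlen + 1)
        events.append(_Del(start=s + 1, length=dlen))
    for ilen in sorted(spec.insertions, reverse=True):
        anchor = place(1)
        events.append(_Ins(anchor=anchor, seq="".join(rng.choice(_BASES) for _ in range(ilen))))
    for _ in range(spec.n_snps):
        pos = place(1)
        alt = rng.choice([b for b in _BASES if b != ref[pos]])
        events.append(_Snp(pos=pos, alt=alt))
    return events, inversion_interval


def _event_pos(event) -> int:
    if isinstance(event, _Snp):
        return event.pos
    if isinstance(event, _Ins):
        return event.anchor
    return event.start


def _build_segment(
    ref: str,
    begin: int,
    end: int,
    events: Sequence,
    contig: str,
    sv_threshold: int,
) -> tuple[str, str, list[VcfRecord]]:
    """Gapped target/query rows and truth variants for colinear ref[begin:end)."""
    t_parts: list[str] = []
    q_parts: list[str] = []
    variants: list[VcfRecord] = []
    cur = begin
    for event in sorted(events, key=_event_pos):
        if isinstance(event, _Snp):
            t_parts.append(ref[cur : event.pos])
            q_parts.append(ref[cur : event.pos])
            t_parts.append(ref[event.pos])
            q_parts.append(event.alt)
            cur = event.pos + 1
            variants.append(
                VcfRecord(contig=contig, pos=event.pos + 1, ref=ref[event.pos], alt=event.alt)
            )
        elif isinstance(event, _Ins):
            t_parts.append(ref[cur : event.anchor + 1])
            q_parts.append(ref[cur : event.anchor + 1])
            t_parts.append("-" * len(event.seq))
            q_parts.append(event.seq)
            cur = event.anchor + 1
            long_enough = len(event.seq) >= sv_threshold
            variants.append(
                VcfRecord(
                    contig=contig,
                    pos=event.anchor + 1,
                    ref=ref[event.anchor],
                    alt=ref[event.anchor] + event.seq,
                    svtype="INS" if long_enough else None,
                    svlen=len(event.seq) if long_enough else None,
                )
            )
        else:  # _Del
            t_parts.append(ref[cur : event.start])
            q_parts.append(ref[cur : event.start])
            t_parts.append(ref[event.start : event.start + event.length])
            q_parts.append("-" * event.length)
            cur = event.start + event.length
            long_enough = event.length >= sv_threshold
            variants.append(
                VcfRecord(
                    contig=contig,
                    pos=event.start,
                    ref=ref[event.start - 1 : event.start + event.length],
                    alt=ref[event.start - 1],
                    svtype="DEL" if long_enough else None,
                    svlen=-event.length if long_enough else None,
                )
            )
    t_parts.append(ref[cur:end])
    q_parts.append(ref[cur:end])
    return "".join(t_parts), "".join(q_parts), variants


def generate_pair(
    ref_length: int,
    spec: MutationSpec,
    ref_name: str = "ref.chr1",
    qry_name: str = "qry.chr1",
    sv_threshold: int = SV_THRESHOLD_DEFAULT,
) -> GenomePair:
    """Generate a (reference, query, truth MAF, truth variants) quadruple.

    Identical arguments always produce identical output.
    """
    if ref_length < 10:
        raise UsageError("reference length must be >= 10")
    rng = random.Random(spec.seed)
    ref = "".join(rng.choice(_BASES) for _ in range(ref_length))
    events, inversion = _place_events(ref, spec, rng)

    def make_block(t_start, t_text, q_start_fwd, q_text, q_strand, q_size):
        q_ungapped = len(ungapped(q_text))
        if q_strand == "+":
            q_maf_start = q_start_fwd
        else:
            q_maf_start = q_size - (q_start_fwd + q_ungapped)
        return MafBlock(
            rows=[
                MafRow(
                    src=ref_name,
                    start=t_start,
                    size=len(ungapped(t_text)),
                    strand="+",
                    src_size=ref_length,
                    text=t_text,
                ),
                MafRow(
                    src=qry_name,
                    start=q_maf_start,
                    size=q_ungapped,
                    strand=q_strand,
                    src_size=q_size,
                    text=q_text,
                ),
            ]
        )

    variants: list[VcfRecord] = []
    if inversion is None:
        t_text, q_text, variants = _build_segment(
            ref, 0, ref_length, events, ref_name, sv_threshold
        )
        qry_seq = ungapped(q_text)
        q_size = len(qry_seq)
        blocks = [make_block(0, t_text, 0, q_text, "+", q_size)]
    else:
        a, b = inversion
        left = [e for e in events if _event_pos(e) < a]
        right = [e for e in events if _event_pos(e) >= b]
        t1, q1, v1 = _build_segment(ref, 0, a, left, ref_name, sv_threshold)
        t3, q3, v3 = _build_segment(ref, b, ref_length, right, ref_name, sv_threshold)
        inv_query_fwd = reverse_complement(ref[a:b])  # the segment as it sits in the query
        q1_len = len(ungapped(q1))
        qry_seq = ungapped(q1) + inv_query_fwd + ungapped(q3)
        q_size = len(qry_seq)
        blocks = [
            make_block(0, t1, 0, q1, "+", q_size),
            # '-' strand row: text is rc(forward query segment) = ref[a:b]
            make_block(a, ref[a:b], q1_len, ref[a:b], "-", q_size),
            make_block(b, t3, q1_len + (b - a), q3, "+", q_size),
        ]
        variants = v1 + v3
        variants.append(
            VcfRecord(
                contig=ref_name,
                pos=a + 1,
                ref=ref[a],
                alt="<INV>",
                svtype="INV",
                svlen=b - a,
                end=b,
                query_name=qry_name,
                query_start=q1_len,
            )
        )
    variants.sort(key=VcfRecord.sort_key)
    return GenomePair(
        ref_name=ref_name,
        qry_name=qry_name,
        ref_seq=ref,
        qry_seq=qry_seq,
        blocks=blocks,
        variants=variants,
        spec=spec,
    )


def write_pair(pair: GenomePair, prefix: str | Path) -> dict[str, Path]:
    """Write .ref.fa, .qry.fa, .truth.maf and .truth.vcf next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": prefix.with_name(prefix.name + ".ref.fa"),
        "qry": prefix.with_name(prefix.name + ".qry.fa"),
        "maf": prefix.with_name(prefix.name + ".truth.maf"),
        "vcf": prefix.with_name(prefix.name + ".truth.vcf"),
    }
    write_fasta({pair.ref_name: pair.ref_seq}, str(paths["ref"]))
    write_fasta({pair.qry_name: pair.qry_seq}, str(paths["qry"]))
    write_maf(pair.blocks, str(paths["maf"]))
    write_vcf(pair.variants, {pair.ref_name: len(pair.ref_seq)}, str(paths["vcf"]))
    return paths
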