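"""Alignment statistics, record filtering, coverage, pseudo-MAF, divergence.

Identity definitions (stated here because the literature varies):

* ``blast_identity``   = matches / aligned columns (gap columns included);
* ``gap_compressed_identity`` = matches / (matches + mismatches + indel
  *events*): each gap run counts once, the convention minimap2 popularized.

The pseudo-MAF is a projection of many query alignments onto reference
coordinates: one fixed-length row per query where each cell holds the
aligned query base, ``x`` for a reference base deleted in the query, or
``-`` for a reference position no block of that query covers. Insertion
columns (gap in the reference) are dropped, which is what keeps every row
exactly region-length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import FormatError, UsageError
from .formats import SequenceStore
from .model import ALIGNED_KINDS, AlignmentRecord, Region

logger = logging.getLogger("wgakit")


@dataclass(frozen=True)
class StatsRow:
    """Per-record summary; counts reconcile with the record's CIGAR stats."""

    query_name: str
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_start: int
    target_end: int
    aligned_columns: int
    matches: int
    mismatches: int
    insertion_events: int
    insertion_bases: int
    deletion_events: int
    deletion_bases: int
    blast_identity: float
    gap_compressed_identity: float

    HEADER = (
        "query_name\tquery_start\tquery_end\tstrand\ttarget_name\ttarget_start"
        "\ttarget_end\taligned_columns\tmatches\tmismatches\tinsertion_events"
        "\tinsertion_bases\tdeletion_events\tdeletion_bases\tblast_identity"
        "\tgap_compressed_identity"
    )

    def to_tsv(self) -> str:
        return (
            f"{self.query_name}\t{self.query_start}\t{self.query_end}\t{self.strand}"
            f"\t{self.target_name}\t{self.target_start}\t{self.target_end}"
            f"\t{self.aligned_columns}\t{self.matches}\t{self.mismatches}"
            f"\t{self.insertion_events}\t{self.insertion_bases}"
            f"\t{self.deletion_events}\t{self.deletion_bases}"
            f"\t{self.blast_identity:.6f}\t{self.gap_compressed_identity:.6f}"
        )


def record_stats(record: AlignmentRecord) -> StatsRow:
    """Pure function of the CIGAR and coordinates. 'M' bases count as matches
    for identity purposes; MAF-derived records never contain 'M'."""
    st = record.cigar.stats()
    matches = st.matches + st.ambiguous
    columns = st.columns
    events = st.insertion_events + st.deletion_events
    denom = matches + st.mismatches + events
    return StatsRow(
        query_name=record.query_name,
        query_start=record.query_start,
        query_end=record.query_end,
        strand=record.strand,
        target_name=record.target_name,
        target_start=record.target_start,
        target_end=record.target_end,
        aligned_columns=columns,
        matches=matches,
        mismatches=st.mismatches,
        insertion_events=st.insertion_events,
        insertion_bases=st.insertion_bases,
        deletion_events=st.deletion_events,
        deletion_bases=st.deletion_bases,
        blast_identity=matches / columns if columns else 0.0,
        gap_compressed_identity=matches / denom if denom else 0.0,
    )


def filter_records(
    records: Iterable[AlignmentRecord],
    min_block_length: int = 0,
    min_query_size: int = 0,
    name_regex: Optional[str] = None,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Keep records with target span >= min_block_length, query size >=
    min_query_size, and (if given) query name matching the regex.

    Returns (kept, tally of rejections by reason); each rejected record is
    tallied under the first failing criterion.
    """
    if name_regex is not None:
        try:
            pattern = re.compile(name_regex)
        except re.error as exc:
            raise UsageError(f"invalid name regex {name_regex!r}: {exc}") from exc
    else:
        pattern = None
    kept: list[AlignmentRecord] = []
    tally = {"short_block": 0, "small_query": 0, "name_mismatch": 0}
    for record in records:
        if record.target_span < min_block_length:
            tally["short_block"] += 1
        elif record.query_size < min_query_size:
            tally["small_query"] += 1
        elif pattern is not None and not pattern.search(record.query_name):
            tally["name_mismatch"] += 1
        else:
            kept.append(record)
    return kept, tally


@dataclass(frozen=True)
class CoverageRow:
    target_name: str
    target_length: int
    covered: int
    fraction: float
    block_count: int

    HEADER = "target_name\ttarget_length\tcovered\tfraction\tblock_count"

    def to_tsv(self) -> str:
        return (
            f"{self.target_name}\t{self.target_length}\t{self.covered}"
            f"\t{self.fraction:.6f}\t{self.block_count}"
        )


def coverage(records: Iterable[AlignmentRecord]) -> list[CoverageRow]:
    """Per-target covered bases = size of the union of target intervals."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    lengths: dict[str, int] = {}
    for record in records:
        name = record.target_name
        if name in lengths and lengths[name] != record.target_size:
            raise FormatError(
                f"conflicting lengths for target {name!r}: "
                f"{lengths[name]} vs {record.target_size}"
            )
        lengths[name] = record.target_size
        intervals.setdefault(name, []).append((record.target_start, record.target_end))
    rows = []
    for name in sorted(intervals):
        merged_total = 0
        cur_start = cur_end = None
        for start, end in sorted(intervals[name]):
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    merged_total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        if cur_end is not None:
            merged_total += cur_end - cur_start
        rows.append(
            CoverageRow(
                target_name=name,
                target_length=lengths[name],
                covered=merged_total,
                fraction=merged_total / lengths[name] if lengths[name] else 0.0,
                block_count=len(intervals[name]),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# pseudo-MAF


NOT_COVERED = "-"
DELETED = "x"


@dataclass
class PseudoMaf:
    """Reference-length projection of query alignments onto one region."""

    region: Region
    reference_row: str
    query_rows: dict[str, str]

    def __post_init__(self) -> None:
        n = self.region.length
        if len(self.reference_row) != n:
            raise FormatError("reference row length disagrees with region length")
        for name, row in self.query_rows.items():
            if len(row) != n:
                raise FormatError(f"pseudo-MAF row for {name!r} has wrong length")


def _project_record(record: AlignmentRecord, region: Region, cells: list[str]) -> int:
    """Fill ``cells`` (region-length list) from one record; returns the number
    of positions that were already filled by another block (conflicts)."""
    if not record.has_texts:
        raise UsageError("pseudo-MAF construction needs sequence-bearing records")
    conflicts = 0
    tpos = record.target_start
    for t_ch, q_ch in zip(record.target_text, record.query_text):
        if t_ch == "-":
            continue  # insertion column: dropped from the projection
        if region.start <= tpos < region.end:
            i = tpos - region.start
            value = DELETED if q_ch == "-" else q_ch
            if cells[i] == NOT_COVERED:
                cells[i] = value
            else:
                conflicts += 1
        tpos += 1
    return conflicts


def build_pseudo_maf(
    ref: SequenceStore,
    records: Sequence[AlignmentRecord],
    region: Region,
    group_key=None,
) -> PseudoMaf:
    """Project ``records`` (all against one reference) onto ``region``.

    ``group_key`` maps a record to its query-genome label (default: the
    record's query name). When two blocks of one query overlap the same
    reference position the longer target span wins; conflicts are logged.
    """
    targets = {r.target_name for r in records}
    if len(targets) > 1:
        raise UsageError(f"records target several sequences: {sorted(targets)}")
    if targets and next(iter(targets)) != region.name:
        raise UsageError(
            f"records target {next(iter(targets))!r} but region names {region.name!r}"
        )
    if group_key is None:
        group_key = lambda r: r.query_name
    grouped: dict[str, list[AlignmentRecord]] = {}
    for record in records:
        grouped.setdefault(group_key(record), []).append(record)
    rows: dict[str, str] = {}
    for name, group in grouped.items():
        cells = [NOT_COVERED] * region.length
        conflicts = 0
        # longer blocks first, so they win overlapped positions
        for record in sorted(group, key=lambda r: -r.target_span):
            conflicts += _project_record(record, region, cells)
        if conflicts:
            logger.warning(
                "pseudo-MAF: %d overlapping position(s) for query %s; longer block kept",
                conflicts,
                name,
            )
        rows[name] = "".join(cells)
    return PseudoMaf(
        region=region,
        reference_row=ref.fetch(region.name, region.start, region.end),
        query_rows=rows,
    )


@dataclass(frozen=True)
class DivergenceRow:
    query: str
    covered: int
    snp_rate: float
    gap_rate: float
    covered_fraction: float

    HEADER = "query\tcovered\tsnp_rate\tgap_rate\tcovered_fraction"

    def to_tsv(self) -> str:
        return (
            f"{self.query}\t{self.covered}\t{self.snp_rate:.6f}"
            f"\t{self.gap_rate:.6f}\t{self.covered_fraction:.6f}"
        )


def divergence(pseudo: PseudoMaf) -> list[DivergenceRow]:
    """SNP and gap divergence per query over its covered positions.

    A query covering nothing reports zero rates with covered = 0 rather than
    NaN, so downstream tables stay numeric.
    """
    rows = []
    ref_row = pseudo.reference_row
    for name, row in pseudo.query_rows.items():
        covered = snps = gaps = 0
        for r_ch, q_ch in zip(ref_row, row):
            if q_ch == NOT_COVERED:
                continue
            covered += 1
            if q_ch == DELETED:
                gaps += 1
            elif q_ch != r_ch:
                snps += 1
        rows.append(
            DivergenceRow(
                query=name,
                covered=covered,
                snp_rate=snps / covered if covered else 0.0,
                gap_rate=gaps / covered if covered else 0.0,
                covered_fraction=covered / pseudo.region.length,
            )
        )
    return rows
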