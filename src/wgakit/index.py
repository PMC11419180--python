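"""MAF indexing, interval-precise extraction, and file splitting.

The index is a JSON sidecar mapping each target sequence (the first 's' row
of every block) to a list of (byte offset of the 'a' line, target start,
target end) entries, sorted by target start. A file fingerprint (byte size)
guards against extraction through a stale index. Indexing requires an
uncompressed MAF because extraction seeks to raw byte offsets.
"""

from __future__ import annotations

import io
import json
import math
import os
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from ._util import GZIP_MAGIC, ungapped
from .errors import FormatError, UsageError
from .formats import MafBlock, MafRow, read_maf, write_maf
from .model import Region

INDEX_SUFFIX = ".index"


@dataclass(frozen=True)
class IndexEntry:
    offset: int
    start: int
    end: int


@dataclass
class MafIndex:
    """Per-target-sequence block directory for one MAF file."""

    fingerprint: int
    entries: dict[str, list[IndexEntry]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "format": "wgakit-maf-index",
            "version": 1,
            "fingerprint": self.fingerprint,
            "targets": {
                name: [[e.offset, e.start, e.end] for e in items]
                for name, items in sorted(self.entries.items())
            },
        }
        return json.dumps(payload, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MafIndex":
        payload = json.loads(text)
        if payload.get("format") != "wgakit-maf-index":
            raise FormatError("not a wgakit MAF index file")
        entries = {
            name: [IndexEntry(*item) for item in items]
            for name, items in payload["targets"].items()
        }
        return cls(fingerprint=payload["fingerprint"], entries=entries)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MafIndex":
        return cls.from_json(Path(path).read_text())

    def lookup(self, region: Region) -> list[IndexEntry]:
        """Entries overlapping ``region``, by bisection on start with a
        max-end guard (entries are sorted by start)."""
        items = self.entries.get(region.name, [])
        if not items:
            return []
        hi = bisect_left([e.start for e in items], region.end)
        hits = []
        for entry in items[:hi]:
            if entry.end > region.start:
                hits.append(entry)
        return hits


def _scan_block_offsets(path: str | Path) -> Iterator[tuple[int, MafRow]]:
    """Yield (byte offset of 'a' line, parsed target row) per block."""
    with open(path, "rb") as fh:
        if fh.read(2) == GZIP_MAGIC:
            raise UsageError(
                "MAF indexing requires an uncompressed file (offsets are byte positions)"
            )
        fh.seek(0)
        offset = 0
        block_offset: Optional[int] = None
        target_row: Optional[MafRow] = None
        for raw in fh:
            line = raw.decode()
            stripped = line.rstrip("\n")
            if stripped.startswith("a") and not stripped.startswith("#"):
                if block_offset is not None and target_row is not None:
                    yield block_offset, target_row
                block_offset, target_row = offset, None
            elif stripped.startswith("s") and block_offset is not None and target_row is None:
                fields = stripped.split()
                if len(fields) != 7:
                    raise FormatError(
                        f"MAF 's' line has {len(fields)} fields, expected 7", str(path)
                    )
                target_row = MafRow(
                    src=fields[1],
                    start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    src_size=int(fields[5]),
                    text=fields[6],
                )
            offset += len(raw)
        if block_offset is not None and target_row is not None:
            yield block_offset, target_row


def build_maf_index(path: str | Path, sidecar: bool = True) -> MafIndex:
    """Index ``path`` by target coordinates; writes ``path + '.index'`` by default."""
    entries: dict[str, list[IndexEntry]] = {}
    for offset, row in _scan_block_offsets(path):
        start, end = row.forward_interval()
        entries.setdefault(row.src, []).append(IndexEntry(offset, start, end))
    for items in entries.values():
        items.sort(key=lambda e: (e.start, e.end, e.offset))
    index = MafIndex(fingerprint=os.path.getsize(path), entries=entries)
    if sidecar:
        index.save(str(path) + INDEX_SUFFIX)
    return index


def _read_block_at(path: str | Path, offset: int) -> MafBlock:
    with open(path, "rb") as fh:
        fh.seek(offset)
        text_stream = io.TextIOWrapper(fh)
        for block in read_maf(text_stream):
            return block
    raise FormatError(f"no MAF block found at offset {offset}", str(path))


def trim_block_to_region(block: MafBlock, region: Region) -> Optional[MafBlock]:
    """Slice a block to the alignment columns whose target coordinate lies in
    ``region``.

    Insertion columns (gap in the target row) stay attached to the kept
    column on their left; insertions before the first kept column are
    dropped. Row starts and sizes are recomputed so the result is again a
    valid block. Returns None when no target column falls in the region.
    """
    target = block.target
    if target.strand != "+":
        raise UsageError("region trimming requires a forward-strand target row")
    first_kept = last_kept = None
    tpos = target.start
    for col, ch in enumerate(target.text):
        if ch == "-":
            continue
        if region.start <= tpos < region.end:
            if first_kept is None:
                first_kept = col
            last_kept = col
        tpos += 1
    if first_kept is None:
        return None
    # extend past trailing insertion columns attached to the last kept column
    end_col = last_kept + 1
    while end_col < block.width and target.text[end_col] == "-":
        end_col += 1
    new_rows = []
    for row in block.rows:
        consumed_before = len(ungapped(row.text[:first_kept]))
        sliced = row.text[first_kept:end_col]
        new_rows.append(
            MafRow(
                src=row.src,
                start=row.start + consumed_before,
                size=len(ungapped(sliced)),
                strand=row.strand,
                src_size=row.src_size,
                text=sliced,
            )
        )
    return MafBlock(rows=new_rows, score=block.score)


def extract_region(
    path: str | Path,
    index: MafIndex,
    region: Region,
    mode: str = "block",
) -> list[MafBlock]:
    """Blocks overlapping ``region``; mode 'trim' slices them to the region."""
    if mode not in ("block", "trim"):
        raise UsageError(f"unknown extraction mode {mode!r} (expected 'block' or 'trim')")
    if os.path.getsize(path) != index.fingerprint:
        raise UsageError(
            f"index out of date for {path} "
            f"(file is {os.path.getsize(path)} bytes, index expects {index.fingerprint})"
        )
    blocks = []
    for entry in index.lookup(region):
        block = _read_block_at(path, entry.offset)
        if mode == "trim":
            trimmed = trim_block_to_region(block, region)
            if trimmed is not None:
                blocks.append(trimmed)
        else:
            blocks.append(block)
    return blocks


def split_maf(
    path: str | Path,
    out_dir: str | Path | None = None,
    chunk_count: Optional[int] = None,
    max_blocks: Optional[int] = None,
) -> list[Path]:
    """Partition blocks in file order into sequential chunk files.

    Exactly one of ``chunk_count`` / ``max_blocks`` must be given; blocks are
    never split and no empty chunk is written. Concatenating the outputs
    re-reads to the input's block sequence.
    """
    if (chunk_count is None) == (max_blocks is None):
        raise UsageError("give exactly one of chunk_count or max_blocks")
    if (chunk_count is not None and chunk_count < 1) or (
        max_blocks is not None and max_blocks < 1
    ):
        raise UsageError("chunk parameter must be >= 1")
    blocks = list(read_maf(str(path)))
    if not blocks:
        return []
    if max_blocks is None:
        per_chunk = max(1, math.ceil(len(blocks) / chunk_count))
    else:
        per_chunk = max_blocks
    path = Path(path)
    out_dir = Path(out_dir) if out_dir is not None else path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = path.name[: -len(".maf")] if path.name.endswith(".maf") else path.name
    outputs = []
    for i, begin in enumerate(range(0, len(blocks), per_chunk), 1):
        out_path = out_dir / f"{stem}.part{i:03d}.maf"
        write_maf(blocks[begin : begin + per_chunk], str(out_path))
        outputs.append(out_path)
    return outputs
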