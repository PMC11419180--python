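"""Independent brute-force oracles used by the tests.

Deliberately naive: column-by-column walks, per-base bitmaps and full-file
scans that do not share code with the implementation they check.
"""

from __future__ import annotations


def column_kinds(target_text: str, query_text: str) -> str:
    """Classify each alignment column independently of the package."""
    out = []
    for t, q in zip(target_text.upper(), query_text.upper()):
        assert not (t == "-" and q == "-")
        if t == "-":
            out.append("I")
        elif q == "-":
            out.append("D")
        elif t == "N" or q == "N":
            out.append("X")
        elif t == q:
            out.append("=")
        else:
            out.append("X")
    return "".join(out)


def compress_kinds(kinds: str) -> str:
    """Run-length encode a per-column kind string into CIGAR text."""
    out = []
    i = 0
    while i < len(kinds):
        j = i
        while j < len(kinds) and kinds[j] == kinds[i]:
            j += 1
        out.append(f"{j - i}{kinds[i]}")
        i = j
    return "".join(out)


def count_kinds(kinds: str) -> dict[str, int]:
    """Per-column counts plus run (event) counts per kind."""
    counts = {k: kinds.count(k) for k in "=XMID"}
    events = {k: 0 for k in "=XMID"}
    prev = None
    for k in kinds:
        if k != prev:
            events[k] += 1
        prev = k
    return {
        "matches": counts["="],
        "mismatches": counts["X"],
        "ambiguous": counts["M"],
        "ins_bases": counts["I"],
        "ins_events": events["I"],
        "del_bases": counts["D"],
        "del_events": events["D"],
        "columns": len(kinds),
    }


def bitmap_covered(intervals: list[tuple[int, int]], length: int) -> int:
    """Per-base bitmap count of covered positions."""
    hit = bytearray(length)
    for start, end in intervals:
        for i in range(start, end):
            hit[i] = 1
    return sum(hit)


def blocks_overlapping(blocks, name: str, start: int, end: int):
    """Brute-force scan: blocks whose target row interval overlaps [start, end)."""
    out = []
    for block in blocks:
        row = block.rows[0]
        if row.src != name:
            continue
        s, e = row.forward_interval()
        if s < end and e > start:
            out.append(block)
    return out
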