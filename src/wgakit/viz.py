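"""Static visualization: dot-plot segments (SVG + TSV) and text block rendering.

Dot plots are built in two stages so they are machine-checkable: records
first become :class:`DotSegment` geometry (exported as headered TSV), and
the SVG renderer then draws one line element per segment. Output is fully
deterministic for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import UsageError
from .formats import MafBlock
from .model import ALIGNED_KINDS, AlignmentRecord, classify_column

SEGMENT_KINDS = ("match", "mismatch", "record")

_KIND_STYLE = {
    "match": "stroke:#1f77b4;stroke-width:1.5",
    "mismatch": "stroke:#d62728;stroke-width:1.5",
    "record": "stroke:#2ca02c;stroke-width:2",
}


@dataclass(frozen=True)
class DotSegment:
    """One plotted segment; q1 < q0 encodes a minus-strand (anti-diagonal) run."""

    target: str
    query: str
    t0: int
    t1: int
    q0: int
    q1: int
    kind: str
    strand: str

    HEADER = "target\tquery\tt0\tt1\tq0\tq1\tkind\tstrand"

    def to_tsv(self) -> str:
        return (
            f"{self.target}\t{self.query}\t{self.t0}\t{self.t1}"
            f"\t{self.q0}\t{self.q1}\t{self.kind}\t{self.strand}"
        )

    @property
    def target_length(self) -> int:
        return abs(self.t1 - self.t0)


def dotplot_segments(
    records: Iterable[AlignmentRecord], mode: str = "overview"
) -> list[DotSegment]:
    """Overview: one segment per record. Base: one segment per aligned run,
    with I/D runs advancing a single axis and emitting nothing."""
    if mode not in ("overview", "base"):
        raise UsageError(f"unknown dot-plot mode {mode!r} (expected 'overview' or 'base')")
    segments: list[DotSegment] = []
    for record in records:
        if mode == "overview":
            if record.strand == "+":
                q0, q1 = record.query_start, record.query_end
            else:
                q0, q1 = record.query_end, record.query_start
            segments.append(
                DotSegment(
                    target=record.target_name,
                    query=record.query_name,
                    t0=record.target_start,
                    t1=record.target_end,
                    q0=q0,
                    q1=q1,
                    kind="record",
                    strand=record.strand,
                )
            )
            continue
        t = record.target_start
        step = 1 if record.strand == "+" else -1
        q = record.query_start if record.strand == "+" else record.query_end
        for op in record.cigar:
            if op.kind in ALIGNED_KINDS:
                kind = "mismatch" if op.kind == "X" else "match"
                segments.append(
                    DotSegment(
                        target=record.target_name,
                        query=record.query_name,
                        t0=t,
                        t1=t + op.length,
                        q0=q,
                        q1=q + step * op.length,
                        kind=kind,
                        strand=record.strand,
                    )
                )
                t += op.length
                q += step * op.length
            elif op.kind == "I":
                q += step * op.length
            else:  # 'D'
                t += op.length
    return segments


def write_segments_tsv(segments: Sequence[DotSegment], dest) -> None:
    from ._util import maybe_close, open_text_output

    stream = open_text_output(dest)
    try:
        stream.write(DotSegment.HEADER + "\n")
        for seg in segments:
            stream.write(seg.to_tsv() + "\n")
    finally:
        stream.flush()
        maybe_close(stream, dest)


def render_svg(
    segments: Sequence[DotSegment], width_px: int = 800, height_px: int = 600
) -> str:
    """Render segments as an SVG document: x = target, y = query coordinates.

    Empty input yields a minimal axes-only document.
    """
    margin = 40.0
    t_max = max((max(s.t0, s.t1) for s in segments), default=1) or 1
    q_max = max((max(s.q0, s.q1) for s in segments), default=1) or 1
    plot_w = width_px - 2 * margin
    plot_h = height_px - 2 * margin

    def sx(t: float) -> float:
        return margin + t / t_max * plot_w

    def sy(q: float) -> float:
        # SVG y grows downward; genome coordinates grow upward
        return height_px - margin - q / q_max * plot_h

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width_px}" '
        f'height="{height_px}" viewBox="0 0 {width_px} {height_px}">',
        f'<rect x="0" y="0" width="{width_px}" height="{height_px}" fill="white"/>',
        # axes
        f'<path d="M {margin:.2f} {margin:.2f} L {margin:.2f} {height_px - margin:.2f} '
        f'L {width_px - margin:.2f} {height_px - margin:.2f}" '
        'fill="none" stroke="black" stroke-width="1"/>',
    ]
    for seg in segments:
        lines.append(
            f'<line x1="{sx(seg.t0):.2f}" y1="{sy(seg.q0):.2f}" '
            f'x2="{sx(seg.t1):.2f}" y2="{sy(seg.q1):.2f}" '
            f'style="{_KIND_STYLE[seg.kind]}"/>'
        )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_block_text(
    block: MafBlock, width: int = 80, highlight: str = "variants"
) -> list[str]:
    """Wrapped, coordinate-annotated text view of one pairwise block.

    With ``highlight='variants'`` each chunk gains a marker line: '*' under
    mismatch columns and '-' under gap columns. Widths below 20 leave no
    room for labels and are rejected.
    """
    if width < 20:
        raise UsageError(f"width must be >= 20, got {width}")
    if highlight not in ("variants", "none"):
        raise UsageError(f"unknown highlight mode {highlight!r}")
    if len(block.rows) != 2:
        raise UsageError("text rendering requires a pairwise block")
    t, q = block.target, block.query
    label_width = max(len(t.src), len(q.src)) + 1 + max(
        len(str(t.start + t.size)), len(str(q.start + q.size))
    )
    chunk = width - label_width - 1
    if chunk < 1:
        raise UsageError(f"width {width} leaves no room for sequence columns")
    out: list[str] = []
    t_pos, q_pos = t.start, q.start  # strand-relative, like the MAF rows
    for begin in range(0, block.width, chunk):
        t_slice = t.text[begin : begin + chunk]
        q_slice = q.text[begin : begin + chunk]
        t_label = f"{t.src} {t_pos}"
        q_label = f"{q.src} {q_pos}"
        out.append(f"{t_label:<{label_width}} {t_slice}")
        out.append(f"{q_label:<{label_width}} {q_slice}")
        if highlight == "variants":
            markers = []
            for t_ch, q_ch in zip(t_slice, q_slice):
                kind = classify_column(t_ch, q_ch)
                if kind == "X":
                    markers.append("*")
                elif kind in ("I", "D"):
                    markers.append("-")
                else:
                    markers.append(" ")
            out.append(" " * (label_width + 1) + "".join(markers).rstrip())
        t_pos += sum(1 for ch in t_slice if ch != "-")
        q_pos += sum(1 for ch in q_slice if ch != "-")
    return out
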