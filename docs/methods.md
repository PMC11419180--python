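# Methods

This note records the models, conventions and numerical choices behind
`wgakit`, in the order a reader meets them: the canonical alignment model,
the per-format coordinate dialects, conversion semantics, indexing,
statistics, variant calling, visualization, and the synthetic data the
tests run on.

## Canonical alignment model

All operations go through one record type: query and target name/size, a
0-based half-open interval on the **forward strand of each sequence**, a
strand flag giving the query's orientation relative to the target, a
normalized CIGAR, and optionally the two gapped alignment rows. The CIGAR
alphabet is `=` (match), `X` (mismatch), `M` (aligned, base identity
unknown), `I` (consumes query only), `D` (consumes target only).
Normalization merges adjacent runs of equal kind, so every CIGAR has a
unique canonical form and expansion/compression is an exact round trip.

Column classification is case-insensitive; `N` against anything — including
another `N` — classifies as a mismatch, because an ambiguous base carries no
evidence of identity. This is a documented, testable choice; alignments of
N-free synthetic sequence are unaffected. A column gapped in both rows is a
format error, as is any character outside `ACGTN-`.

When texts are present the record is self-consistent by construction: the
column classes of the texts must reproduce the stored CIGAR (`M` accepts
any base-against-base column), and the ungapped text lengths must equal the
interval spans. Violations raise immediately rather than propagating.

`M` handling is resolve-when-possible: any conversion with sequence in hand
(MAF ingest, FASTA-backed reconstruction) replaces `M` by `=`/`X`;
sequence-free paths (PAF↔Chain without FASTA) pass `M` through untouched, so
no information is invented or destroyed.

## Coordinate dialects

Fixed at the format boundary, nowhere else:

| format | query interval convention |
|---|---|
| MAF | row start is strand-relative: a `-` row counts from the reverse-complemented sequence |
| PAF | always forward-strand |
| Chain | minus-strand query coordinates are reverse-complement-relative; target strand always `+` |

The single identity `forward_start = size − (rc_start + span)` converts
between the dialects; it is exercised by every minus-strand test. MAF
blocks whose *target* row is on `-` are normalized on ingest by
reverse-complementing both rows (flipping both strands), with a logged
warning.

Pairwise MAF row order is reference-first (row 0 = target). Readers accept
blocks with more rows, converters require exactly two.

## Conversion semantics

Conversion is hub-and-spoke: each format maps to/from the canonical record,
never directly to another format. Choices the chain grammar forced:

- **Edge indels.** A chain must start and end with a gapless block, so
  leading/trailing `I`/`D` runs are folded into the interval endpoints
  before emission (query-side trimming is strand-aware: on `-` records a
  leading `I` comes off the forward-strand end). The same trimming applies
  to MAF/PAF emission so the three outputs describe the same alignment.
  Trims are logged; the synthetic generator never produces edge indels, so
  round-trip tests are exact.
- **Gap lines.** Adjacent `I`-then-`D` (or reverse) runs share one
  `(size, dt, dq)` line; the chain grammar does not order the two gaps, so
  re-expansion emits `D` before `I`. Order information inside one gap line
  is the only thing a sequence-free PAF→Chain→PAF trip can lose, and only
  for directly adjacent indels.
- **Chain score.** Undefined by the format description we target; we use
  the residue-match count when the CIGAR distinguishes `=`/`X`, else the
  aligned-base count of an all-`M` CIGAR. Deterministic, documented, not
  claimed to match any other tool.
- **Chain ids** are assigned sequentially from 1 in input order.
- **PAF residue matches** count `=` bases plus unresolved `M` bases (the
  format cannot distinguish them without sequence); block length is the
  aligned-column count; missing mapping quality is written as 255.
- **MAF scores** are not carried through the canonical record: a
  `paf2maf`/`chain2maf` output has no `a score=` field, and a MAF→PAF→MAF
  trip loses the score. Accepted limitation — neither PAF nor our record
  has a slot for it.

## MAF index

The sidecar (`<file>.index`, JSON) maps each target name to
`(byte offset of the 'a' line, target start, target end)` per block, sorted
by start. The fingerprint is the file's byte size — cheap and sufficient to
catch the accidental-edit case the tests exercise; it is not a content
hash. Lookup bisects on start below the region end and filters by end; the
test of record is equivalence with a linear scan, not the asymptotics.
Indexing refuses gzip input because offsets address the uncompressed byte
stream.

Trim-mode extraction keeps the alignment columns whose target coordinate
falls in the region; insertion columns (target gap) stay attached to the
kept column on their left, and insertions before the first kept column are
dropped. This keeps the target-interval semantics of the result exact at
the cost of occasionally dropping a leading insertion — the alternative
(attach right) would let trimmed blocks leak past the region start.

## Statistics

- `blast_identity = matches / aligned_columns` (gap columns in the
  denominator).
- `gap_compressed_identity = matches / (matches + mismatches + indel
  events)` — each gap run counts once. Event-based, not base-based: one
  60 bp insertion should not cost sixty times one 1 bp insertion.
- Unresolved `M` bases count as matches in both identities; MAF-derived
  records never contain `M`.

Coverage is the size of the union of target intervals (merged sweep), with
conflicting target sizes for one name rejected.

The pseudo-MAF projects query alignments onto a reference window: one
region-length row per query, each cell the aligned query base, `x` for a
reference base deleted in the query, `-` for an uncovered position.
Insertions relative to the reference are dropped — that is what keeps rows
reference-length; a union-gap MSA is out of scope. `x` vs `-` matters
because divergence is computed over covered positions only: `snp_rate` =
mismatching bases / covered, `gap_rate` = `x` / covered,
`covered_fraction` = covered / region length. A fully uncovered query
reports zero rates with `covered = 0` rather than NaN. When two blocks of
one query overlap a reference position, the longer target span wins and the
conflict is logged.

## Variant calling

Per resolved CIGAR run: `X` → one SNP per column (no MNP merging); `I` →
one insertion anchored on the target base immediately left of the run
(REF = anchor, ALT = anchor + inserted bases); `D` → one deletion
(REF = anchor + deleted bases, ALT = anchor). Placement is taken from the
input alignment as-is; no left-alignment beyond the anchor. Runs of
≥ `sv_threshold` (default 50 bp, the usual indel/SV boundary) gain
`SVTYPE`/`SVLEN` (+L insertions, −L deletions). An indel run at the very
start of an alignment has no anchor and is skipped with a warning tally.

Inversions are called from strand signatures only: a minus-strand record
flanked on both sides (in target coordinates) by plus-strand records of the
same query/target pair yields one symbolic `<INV>` record spanning its
target interval. A lone minus-strand record is not called — without
flanking colinear alignment there is no evidence the segment is inverted in
place rather than simply mapped from elsewhere. No other structural classes
(duplication, translocation) are attempted.

The calls are self-validating: replaying SNP/INS/DEL records onto the
target subsequence must rebuild the (alignment-oriented) query subsequence
exactly; this oracle runs in the test suite and the acceptance script over
every sequence-bearing record.

## Visualization

Dot plots are computed as geometry first (segment list: target/query
endpoint pairs, kind ∈ {match, mismatch, record}, anti-diagonal for `-`
strand) and rendered second, so the plot content is testable as TSV
independent of SVG serialization. Base mode emits one segment per aligned
run; `I`/`D` runs advance one axis silently, which makes the endpoint gaps
between consecutive segments equal the intervening indel lengths — a tested
invariant. Interactive viewing (drag/zoom, terminal UI loops) is replaced
by this deterministic static core on purpose: it is the computable part,
and it cannot drift between runs.

## Synthetic genome pairs

The generator draws a uniform-random ACGT reference and plants events by
rejection sampling under a caller-supplied seed: SNP alt bases uniform over
the three non-reference bases, insertion content uniform ACGT. Event
footprints (anchor included) stay ≥ 2 bp apart and ≥ 1 bp from the sequence
ends, so every indel keeps its own anchor, no alignment starts or ends in
an indel, and truth variants never interact. An inversion is emitted as
three truth blocks (`+`, `-`, `+`) with the middle block's query row in
reverse-complement coordinates — precisely the signature the inversion
caller consumes. The truth MAF and truth VCF are derived from the same
construction walk, so generator and caller conventions agree by
construction, and `call_variants(truth MAF) == truth VCF` is a meaningful
end-to-end check rather than a tautology: it exercises the MAF writer and
reader, strand arithmetic, the column walk and the calling logic.

Default study conditions used by the tests and the acceptance script:
1 kb reference; 20 SNPs; three insertions and three deletions with lengths
uniform in 1–80 bp (spanning both sides of the 50 bp SV threshold); 40 bp
inversions where planted; 200 pairs for round-trip measurements, 10 for
truth recovery, 100 random interval sets / regions for the coverage and
extraction oracles. These sizes keep the full suite in seconds while every
code path (minus strand, SV annotation, multi-block queries) is hit.

What the generator does **not** emulate — and therefore what passing tests
do not show: realistic mutation rates or spectra, repeats and segmental
duplications (so no ambiguous mappings), overlapping or nested events,
breakpoint microhomology, N bases, and aligner noise (the truth MAF is a
perfect alignment; real aligner output may place indels differently, and
calls will follow that placement).

## Known limitations

- Conversions require pairwise blocks; multi-row MAF algebra is out of
  scope.
- MAF `a score=` values do not survive conversion (see above).
- Random access works on uncompressed MAF only; gzip inputs are streamed.
- Sequence-free PAF→Chain→PAF cannot restore the order of directly
  adjacent I/D runs or distinguish `=`/`X` inside an `M` run.
- Inversion calling is a heuristic over strand patterns; nested or
  unflanked inversions are not reported.
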