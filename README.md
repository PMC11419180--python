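# wgakit

Whole-genome alignment (WGA) pipelines speak three mutually incompatible
dialects: **MAF** (blocks of gapped sequence rows with strand-relative
starts), **PAF** (12 tab-separated columns plus a `cg:Z:` CIGAR tag, with
forward-strand query intervals) and **UCSC Chain** (gapless blocks linked by
`size dt dq` triples, with reverse-complement-relative minus-strand
coordinates). Comparative genomicists routinely need to move one alignment
between all three — to lift annotations, call variants, compute coverage or
just feed the next tool — without corrupting a single coordinate.

`wgakit` is a Python library and CLI for exactly that workflow:

- **lossless conversion** among MAF, PAF and Chain through one canonical
  pairwise alignment record (hub-and-spoke: six composite conversions, two
  spokes each), reconstructing sequence text from FASTA when the
  destination needs it;
- **MAF indexing** (JSON sidecar of byte offsets keyed by target
  coordinates), interval-precise extraction and sequential splitting;
- **statistics and filtering**: per-record match/mismatch/indel counts,
  BLAST and gap-compressed identity, per-target coverage, reference-frame
  pseudo-MAF projection and SNP/gap divergence;
- **variant calling** from alignment signatures — SNPs, left-anchored
  insertions and deletions (annotated `SVTYPE`/`SVLEN` at ≥ 50 bp), and
  inversions from strand-flip signatures — written as VCF v4.2;
- **visualization**: dot-plot geometry at overview or base resolution
  (SVG + machine-checkable segment TSV) and a plain-text block view;
- a **deterministic synthetic genome-pair generator** that plants known
  SNPs/insertions/deletions/inversions and emits the exact truth MAF and
  truth VCF its construction implies — the substrate on which everything
  above is tested.

## The model in brief

Every alignment is normalized to a record
`(query, q_start, q_end, strand, target, t_start, t_end, CIGAR)` with
0-based half-open intervals on the **forward** strand of both sequences and
an extended CIGAR over `{=, X, M, I, D}` (`I` consumes query only, `D`
consumes target only — the PAF/minimap2 reading). Strand-relative dialects
exist only at format boundaries, linked by the identity

```
forward_start = size − (strand_relative_start + span)
```

MAF carries no CIGAR, so it is derived by a column walk (`=` equal bases,
`X` differing or `N`, `I` gap in target, `D` gap in query); Chain carries no
base detail, so its blocks become `M` runs that resolve to `=`/`X` whenever
FASTA is supplied. Key invariants, enforced on every record:
`q_end − q_start` = query bases consumed, `t_end − t_start` = target bases
consumed, and `query-consumed + D bases = target-consumed + I bases =
aligned columns`.

## Worked example

A 10-column toy alignment (target `ACGTACGTAC`, query `ACGTTCTAC`, one
substitution and one deleted base):

```
$ cat toy.maf
##maf version=1
a
s ref.chr1 0 10 + 10 ACGTACGTAC
s qry.chr1 0 9 + 9 ACGTTC-TAC
```

The column walk gives CIGAR `4=1X1=1D3=` — 8 matched columns, 1 mismatch,
1 single-base deletion:

```
$ wgakit maf2paf toy.maf
qry.chr1  9  0  9  +  ref.chr1  10  0  10  8  10  255  cg:Z:4=1X1=1D3=
```

(column 10 = 8 residue matches, column 11 = 10 aligned columns). The same
alignment as a chain — two gapless blocks of 6 and 3 bases separated by a
1 bp target gap (`dt=1`):

```
$ wgakit maf2chain toy.maf
chain 8 ref.chr1 10 + 0 10 qry.chr1 9 + 0 9 1
6  1  0
3
```

Variant calling emits the SNP at position 5 and the left-anchored deletion
at position 6 (REF `CG` → ALT `C`):

```
$ wgakit call toy.maf | grep -v '^#'
ref.chr1  5  .  A   T  .  PASS  .
ref.chr1  6  .  CG  C  .  PASS  .
```

and the statistics line reports blast identity 8/10 = 0.8 and
gap-compressed identity 8/(8+1+1) = 0.8:

```
$ wgakit stat toy.maf | cut -f8-16
10  8  1  0  0  1  1  0.800000  0.800000
```

Synthetic fixtures with planted truth come from the same package:

```
$ wgakit synth --length 1000 --snps 20 --ins 7,60 --dels 4,55 --inversion 40 \
        --seed 42 --out-prefix demo
```

writes `demo.ref.fa`, `demo.qry.fa`, `demo.truth.maf`, `demo.truth.vcf`;
`wgakit call demo.truth.maf` reproduces `demo.truth.vcf` record for record.

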