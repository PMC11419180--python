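"""MAF/PAF/Chain/FASTA/VCF reading and writing."""

import gzip
import io

import pytest

from conftest import TOY_MAF
from wgakit import (
    ChainRecord,
    FormatError,
    MafBlock,
    MafRow,
    SequenceStore,
    read_chain,
    read_maf,
    read_paf,
    write_chain,
    write_maf,
    write_paf,
    write_vcf,
)
from wgakit.variants import VcfRecord

TOY_PAF = "qry.chr1\t9\t0\t9\t+\tref.chr1\t10\t0\t10\t8\t10\t255\tcg:Z:4=1X1=1D3=\n"
TOY_CHAIN = "chain 8 ref.chr1 10 + 0 10 qry.chr1 9 + 0 9 1\n6\t1\t0\n3\n\n"


class TestMaf:
    def test_parse_toy_block(self):
        block = next(read_maf(io.StringIO(TOY_MAF)))
        assert len(block.rows) == 2
        assert block.rows[0].size == 10
        assert block.rows[1].size == 9
        assert block.rows[0].src == "ref.chr1"

    def test_empty_file_yields_nothing(self):
        assert list(read_maf(io.StringIO(""))) == []

    def test_read_write_round_trip(self):
        blocks = list(read_maf(io.StringIO(TOY_MAF)))
        buf = io.StringIO()
        write_maf(blocks, buf)
        assert list(read_maf(io.StringIO(buf.getvalue()))) == blocks

    def test_write_read_byte_identity_on_normalized_file(self, tmp_path):
        blocks = list(read_maf(io.StringIO(TOY_MAF)))
        path = tmp_path / "a.maf"
        write_maf(blocks, str(path))
        text = path.read_text()
        buf = io.StringIO()
        write_maf(read_maf(io.StringIO(text)), buf)
        assert buf.getvalue() == text

    def test_inconsistent_size_reports_line_number(self):
        bad = "a\ns ref.chr1 0 9 + 10 ACGTACGTAC\ns qry.chr1 0 9 + 9 ACGTTC-TAC\n"
        with pytest.raises(FormatError, match="line 2"):
            list(read_maf(io.StringIO(bad)))

    def test_single_row_block_skipped_with_warning(self, caplog):
        text = "a\ns ref.chr1 0 4 + 10 ACGT\n\n" + TOY_MAF
        with caplog.at_level("WARNING", logger="wgakit"):
            blocks = list(read_maf(io.StringIO(text)))
        assert len(blocks) == 1
        assert "skipping" in caplog.text

    def test_gzip_input_detected_by_magic(self, tmp_path):
        path = tmp_path / "a.maf.gz"
        path.write_bytes(gzip.compress(TOY_MAF.encode()))
        blocks = list(read_maf(str(path)))
        assert len(blocks) == 1 and blocks[0].rows[0].size == 10

    def test_minus_row_forward_interval(self):
        row = MafRow(src="q", start=2, size=5, strand="-", src_size=9, text="ACGTA")
        assert row.forward_interval() == (2, 7)

    def test_reader_is_streaming(self):
        """The reader yields blocks one at a time from a generator, without
        materializing the file."""
        n_blocks = 10_000
        text = TOY_MAF * n_blocks
        it = read_maf(io.StringIO(text))
        assert next(it).rows[0].size == 10  # first block available immediately
        assert sum(1 for _ in it) == n_blocks - 1


class TestPaf:
    def test_parse_toy_line(self):
        rec = next(read_paf(io.StringIO(TOY_PAF)))
        assert rec.residue_matches == 8
        assert rec.block_length == 10
        assert str(rec.cigar) == "4=1X1=1D3="

    def test_eleven_columns_rejected_with_line(self):
        bad = "\t".join(TOY_PAF.split("\t")[:11]) + "\n"
        with pytest.raises(FormatError, match="line 1"):
            list(read_paf(io.StringIO(bad)))

    def test_record_without_cg_has_no_cigar(self):
        line = "\t".join(TOY_PAF.rstrip("\n").split("\t")[:12]) + "\n"
        rec = next(read_paf(io.StringIO(line)))
        assert rec.cigar is None

    def test_illegal_cigar_op_rejected(self):
        bad = TOY_PAF.replace("cg:Z:4=1X1=1D3=", "cg:Z:4=1S")
        with pytest.raises(FormatError):
            list(read_paf(io.StringIO(bad)))

    def test_unknown_tags_survive_round_trip(self):
        line = TOY_PAF.rstrip("\n") + "\ttp:A:P\tzz:i:7\n"
        rec = next(read_paf(io.StringIO(line)))
        buf = io.StringIO()
        write_paf([rec], buf)
        assert buf.getvalue() == line


class TestChain:
    def test_parse_toy_chain(self):
        rec = next(read_chain(io.StringIO(TOY_CHAIN)))
        assert rec.lines == [(6, 1, 0), (3, 0, 0)]
        assert sum(s for s, _, _ in rec.lines) == 9
        assert sum(dt for _, dt, _ in rec.lines) == 1
        assert sum(dq for _, _, dq in rec.lines) == 0

    def test_sum_mismatch_rejected(self):
        bad = TOY_CHAIN.replace("6\t1\t0", "6\t2\t0")
        with pytest.raises(FormatError, match="chain 1"):
            list(read_chain(io.StringIO(bad)))

    def test_query_sum_mismatch_rejected(self):
        bad = "chain 8 ref.chr1 10 + 0 10 qry.chr1 9 + 0 8 1\n6\t1\t0\n3\n\n"
        with pytest.raises(FormatError, match="chain 1"):
            list(read_chain(io.StringIO(bad)))

    def test_final_line_with_three_fields_rejected(self):
        bad = "chain 8 ref.chr1 10 + 0 10 qry.chr1 9 + 0 9 1\n6\t1\t0\n3\t0\t0\n\n"
        with pytest.raises(FormatError):
            list(read_chain(io.StringIO(bad)))

    def test_write_read_byte_identity(self):
        recs = list(read_chain(io.StringIO(TOY_CHAIN)))
        buf = io.StringIO()
        write_chain(recs, buf)
        text = buf.getvalue()
        buf2 = io.StringIO()
        write_chain(read_chain(io.StringIO(text)), buf2)
        assert buf2.getvalue() == text

    def test_minus_strand_forward_interval(self):
        rec = ChainRecord(
            score=5,
            target_name="t",
            target_size=10,
            target_start=0,
            target_end=5,
            query_name="q",
            query_size=20,
            query_strand="-",
            query_start=2,
            query_end=7,
            chain_id=1,
            lines=[(5, 0, 0)],
        )
        assert rec.forward_query_interval() == (13, 18)


class TestSequenceStore:
    def test_fetch_length_and_revcomp_involution(self):
        store = SequenceStore({"s": "ACGTTGCA"})
        sub = store.fetch("s", 2, 6)
        assert len(sub) == 4
        rc = store.fetch("s", 2, 6, "-")
        from wgakit._util import reverse_complement

        assert reverse_complement(rc) == sub

    def test_missing_sequence_named_in_error(self):
        store = SequenceStore({"s": "ACGT"})
        with pytest.raises(FormatError, match="nope"):
            store.fetch("nope", 0, 1)

    def test_out_of_bounds_rejected(self):
        store = SequenceStore({"s": "ACGT"})
        with pytest.raises(FormatError):
            store.fetch("s", 0, 5)

    def test_from_fasta(self, tmp_path):
        path = tmp_path / "x.fa"
        path.write_text(">s1\nACGT\nACGT\n>s2\nTTTT\n")
        store = SequenceStore.from_fasta(str(path))
        assert store.fetch("s1", 0, 8) == "ACGTACGT"
        assert store.length("s2") == 4


class TestVcfWriter:
    def test_snp_body_line_and_header(self):
        buf = io.StringIO()
        rec = VcfRecord(contig="ref.chr1", pos=5, ref="A", alt="T")
        write_vcf([rec], {"ref.chr1": 10}, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        body = [l for l in lines if not l.startswith("#")]
        assert body == ["ref.chr1\t5\t.\tA\tT\t.\tPASS\t."]

    def test_empty_record_list_is_header_only(self):
        buf = io.StringIO()
        write_vcf([], {"c": 5}, buf)
        assert all(l.startswith("#") for l in buf.getvalue().splitlines())

    def test_unsorted_input_rejected(self):
        from wgakit import UsageError

        records = [
            VcfRecord(contig="c", pos=9, ref="A", alt="T"),
            VcfRecord(contig="c", pos=3, ref="G", alt="C"),
        ]
        with pytest.raises(UsageError):
            write_vcf(records, {"c": 10}, io.StringIO())

    def test_output_parses_with_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "x.vcf"
        records = [
            VcfRecord(contig="c", pos=3, ref="G", alt="C"),
            VcfRecord(contig="c", pos=6, ref="ACG", alt="A", svtype="DEL", svlen=-60),
        ]
        # 60 bp deletion in symbolic-free representation: REF 61 bases, ALT 1
        long_ref = "A" + "C" * 60
        records[1] = VcfRecord(contig="c", pos=6, ref=long_ref, alt="A", svtype="DEL", svlen=-60)
        write_vcf(records, {"c": 100}, str(path))
        parsed = list(pysam.VariantFile(str(path)))
        assert len(parsed) == 2
        assert parsed[1].info["SVLEN"] == -60
        assert len(parsed[1].ref) == 61 and len(parsed[1].alts[0]) == 1
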