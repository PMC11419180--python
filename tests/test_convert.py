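"""Hub-and-spoke conversion among MAF, PAF and Chain."""

import io

import pytest

from wgakit import (
    Cigar,
    CigarOp,
    FormatError,
    MafBlock,
    MafRow,
    MissingCigarError,
    SequenceStore,
    read_maf,
)
from wgakit.convert import (
    alignment_to_chain,
    alignment_to_maf,
    alignment_to_paf,
    chain_to_alignment,
    maf_to_alignment,
    paf_to_alignment,
    trim_edge_indels,
)
from wgakit._util import reverse_complement


class TestMafToAlignment:
    def test_toy_block(self, toy_block):
        a = maf_to_alignment(toy_block)
        assert (a.query_name, a.query_start, a.query_end, a.strand) == ("qry.chr1", 0, 9, "+")
        assert (a.target_name, a.target_start, a.target_end) == ("ref.chr1", 0, 10)
        assert str(a.cigar) == "4=1X1=1D3="

    def test_minus_strand_start_converted_to_forward(self):
        # query row "s qry.chr1 2 5 - 9 ..." -> forward interval [2, 7)
        ref = "ACGTA"
        qry_fwd = "TACGT"  # arbitrary; aligned text is its reverse complement
        block = MafBlock(
            rows=[
                MafRow("ref.chr1", 0, 5, "+", 5, ref),
                MafRow("qry.chr1", 2, 5, "-", 9, reverse_complement(qry_fwd)),
            ]
        )
        a = maf_to_alignment(block)
        assert (a.query_start, a.query_end, a.strand) == (2, 7, "-")

    def test_identity_block(self):
        block = MafBlock(
            rows=[MafRow("t", 0, 4, "+", 4, "ACGT"), MafRow("q", 0, 4, "+", 4, "ACGT")]
        )
        assert str(maf_to_alignment(block).cigar) == "4="

    def test_minus_target_row_flipped_to_forward(self):
        # target on '-' is normalized: both strands flip, alignment content preserved
        block = MafBlock(
            rows=[
                MafRow("t", 0, 4, "-", 10, "ACGT"),
                MafRow("q", 1, 4, "+", 8, "ACGT"),
            ]
        )
        a = maf_to_alignment(block)
        assert (a.target_start, a.target_end) == (6, 10)
        assert a.strand == "-"
        assert str(a.cigar) == "4="

    def test_three_row_block_rejected(self):
        rows = [MafRow("a", 0, 2, "+", 2, "AC")] * 3
        with pytest.raises(FormatError):
            maf_to_alignment(MafBlock(rows=rows))


class TestAlignmentToPaf:
    def test_toy_fields(self, toy_record):
        p = alignment_to_paf(toy_record)
        assert p.residue_matches == 8
        assert p.block_length == 10
        assert p.query_end - p.query_start == 9
        assert p.target_end - p.target_start == 10
        assert p.mapping_quality == 255

    def test_pure_match_matches_equal_block_length(self):
        from wgakit import AlignmentRecord

        a = AlignmentRecord("q", 7, 0, 7, "+", "t", 7, 0, 7, Cigar.from_string("7="))
        p = alignment_to_paf(a)
        assert p.residue_matches == p.block_length == 7

    def test_minus_strand_keeps_forward_query_interval(self, pair_factory):
        pair = pair_factory(3, with_inversion=True)
        inv = [a for a in pair.alignments() if a.strand == "-"][0]
        p = alignment_to_paf(inv)
        assert (p.query_start, p.query_end) == (inv.query_start, inv.query_end)
        assert p.strand == "-"


class TestPafToAlignment:
    def test_texts_reconstructed_from_fasta(self, toy_record, toy_store):
        p = alignment_to_paf(toy_record)
        a = paf_to_alignment(p, toy_store)
        assert a.target_text == "ACGTACGTAC"
        assert a.query_text == "ACGTTC-TAC"

    def test_without_store_texts_absent(self, toy_record):
        a = paf_to_alignment(alignment_to_paf(toy_record))
        assert not a.has_texts

    def test_missing_cg_rejected(self, toy_record):
        p = alignment_to_paf(toy_record)
        p.tags = []
        with pytest.raises(MissingCigarError):
            paf_to_alignment(p)

    def test_span_disagreement_rejected(self, toy_record):
        p = alignment_to_paf(toy_record)
        p.tags = ["cg:Z:9="]  # consumes 9/9, but target span is 10
        with pytest.raises(FormatError):
            paf_to_alignment(p)


class TestAlignmentToChain:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("4=1X1=1D3=", [(6, 1, 0), (3, 0, 0)]),
            ("10=", [(10, 0, 0)]),
            ("5=2I3D5=", [(5, 3, 2), (5, 0, 0)]),
        ],
    )
    def test_run_merge(self, cigar, expected):
        from wgakit import AlignmentRecord

        c = Cigar.from_string(cigar)
        a = AlignmentRecord(
            "q", c.query_consumed, 0, c.query_consumed, "+",
            "t", c.target_consumed, 0, c.target_consumed, c,
        )
        assert alignment_to_chain(a, 1).lines == expected

    def test_chain_arithmetic_holds(self, pair_factory):
        for seed in range(1, 6):
            for a in pair_factory(seed, with_inversion=(seed % 2 == 0)).alignments():
                ch = alignment_to_chain(a, 1)
                assert sum(s for s, _, _ in ch.lines) + sum(dt for _, dt, _ in ch.lines) == (
                    ch.target_end - ch.target_start
                )
                assert sum(s for s, _, _ in ch.lines) + sum(dq for _, _, dq in ch.lines) == (
                    ch.query_end - ch.query_start
                )

    def test_minus_strand_chain_coordinates_are_rc_relative(self, pair_factory):
        pair = pair_factory(4, with_inversion=True)
        inv = [a for a in pair.alignments() if a.strand == "-"][0]
        ch = alignment_to_chain(inv, 7)
        assert ch.query_strand == "-"
        assert ch.query_start == inv.query_size - inv.query_end
        assert ch.query_end == inv.query_size - inv.query_start


class TestChainToAlignment:
    def test_without_store_yields_m_runs(self, toy_record):
        ch = alignment_to_chain(toy_record, 1)
        a = chain_to_alignment(ch)
        assert str(a.cigar) == "6M1D3M"

    def test_with_store_resolves_to_match_mismatch(self, toy_record, toy_store):
        ch = alignment_to_chain(toy_record, 1)
        a = chain_to_alignment(ch, toy_store)
        assert str(a.cigar) == "4=1X1=1D3="

    def test_single_line_chain(self):
        from wgakit import ChainRecord

        ch = ChainRecord(
            score=10, target_name="t", target_size=10, target_start=0, target_end=10,
            query_name="q", query_size=10, query_strand="+", query_start=0,
            query_end=10, chain_id=1, lines=[(10, 0, 0)],
        )
        assert str(chain_to_alignment(ch).cigar) == "10M"


class TestEdgeIndelTrimming:
    def test_leading_and_trailing_runs_folded_into_intervals(self):
        from wgakit import AlignmentRecord

        c = Cigar.from_string("2I5=3D")
        a = AlignmentRecord("q", 10, 0, 7, "+", "t", 10, 0, 8, c)
        trimmed, trim = trim_edge_indels(a)
        assert str(trimmed.cigar) == "5="
        assert (trimmed.query_start, trimmed.query_end) == (2, 7)
        assert (trimmed.target_start, trimmed.target_end) == (0, 5)
        assert trim.leading_query == 2 and trim.trailing_target == 3

    def test_minus_strand_leading_insertion_trims_forward_end(self):
        from wgakit import AlignmentRecord

        c = Cigar.from_string("2I5=")
        a = AlignmentRecord("q", 10, 0, 7, "-", "t", 10, 0, 5, c)
        trimmed, _ = trim_edge_indels(a)
        assert (trimmed.query_start, trimmed.query_end) == (0, 5)

    def test_all_indel_cigar_rejected(self):
        from wgakit import AlignmentRecord

        a = AlignmentRecord("q", 5, 0, 5, "+", "t", 5, 0, 5,
                            Cigar([CigarOp("I", 5), CigarOp("D", 5)]))
        with pytest.raises(FormatError):
            trim_edge_indels(a)


class TestRoundTrips:
    """The six composite conversions are exact inverses on fixture blocks."""

    def test_maf_alignment_maf_identity(self, pair_factory):
        for seed in (1, 2):
            for block in pair_factory(seed, with_inversion=True).blocks:
                assert alignment_to_maf(maf_to_alignment(block)) == block

    def test_paf_maf_paf_via_fasta(self, pair_factory):
        pair = pair_factory(5)
        store = pair.store()
        for a in pair.alignments():
            p = alignment_to_paf(a)
            back = alignment_to_paf(maf_to_alignment(alignment_to_maf(paf_to_alignment(p, store))))
            assert back == p

    def test_paf_chain_paf_m_preserving_without_sequence(self):
        from wgakit import AlignmentRecord

        c = Cigar.from_string("6M1D3M")
        a = AlignmentRecord("q", 9, 0, 9, "+", "t", 10, 0, 10, c)
        p = alignment_to_paf(a)
        back = alignment_to_paf(chain_to_alignment(alignment_to_chain(paf_to_alignment(p), 1)))
        assert back == p

    def test_conversion_conserves_cigar_totals(self, pair_factory):
        pair = pair_factory(6)
        store = pair.store()
        for a in pair.alignments():
            st = a.cigar.stats()
            for other in (
                paf_to_alignment(alignment_to_paf(a), store),
                chain_to_alignment(alignment_to_chain(a, 1), store),
                maf_to_alignment(alignment_to_maf(a)),
            ):
                st2 = other.cigar.stats()
                assert st2.matches + st2.mismatches + st2.ambiguous == (
                    st.matches + st.mismatches + st.ambiguous
                )
                assert st2.insertion_bases == st.insertion_bases
                assert st2.deletion_bases == st.deletion_bases
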