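import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicelab.genome import load_fasta, load_gtf
from splicelab.junctions import (CigarError, Junction, anchor_region,
                                 count_exons, count_junctions, donor_window,
                                 junctions_from_cigar)

# -- CIGAR walking ----------------------------------------------------


def naive_cigar_walk(pos, cigar):
    """Independent re-walk: expand the CIGAR op by op."""
    introns, cursor = [], pos
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op == "N":
            introns.append((cursor, cursor + n))
        if op in "MDN=X":
            cursor += n
    return introns


class TestJunctionsFromCigar:
    @pytest.mark.parametrize("pos,cigar,expected", [
        (100, "10M100N10M", [(110, 210)]),
        (0, "20M", []),
        (50, "5M10N5M20N5M", [(55, 65), (70, 90)]),
        (10, "3S10M5I10N2M", [(20, 30)]),  # S and I do not consume reference
    ])
    def test_examples(self, pos, cigar, expected):
        assert junctions_from_cigar(pos, cigar) == expected

    def test_malformed_cigar_rejected(self):
        with pytest.raises(CigarError):
            junctions_from_cigar(0, "10M5Q")

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000),
           st.lists(st.tuples(st.integers(1, 200),
                              st.sampled_from("MIDNSH=X")), min_size=1, max_size=12))
    def test_matches_naive_oracle(self, pos, ops):
        cigar = "".join(f"{n}{op}" for n, op in ops)
        assert junctions_from_cigar(pos, cigar) == naive_cigar_walk(pos, cigar)


# -- counting on a hand-written SAM fixture ---------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:400\n"
#                          111111111122222...          genes: A [50,250)+, B [260,380)+
GTF = """\
chrT\ts\tgene\t51\t250\t.\t+\t.\tgene_id "A";
chrT\ts\texon\t51\t110\t.\t+\t.\tgene_id "A"; transcript_id "tA";
chrT\ts\texon\t211\t250\t.\t+\t.\tgene_id "A"; transcript_id "tA";
chrT\ts\tgene\t261\t380\t.\t+\t.\tgene_id "B";
chrT\ts\texon\t261\t380\t.\t+\t.\tgene_id "B"; transcript_id "tB";
"""


def sam_line(name, pos0, cigar, seq="A" * 20, flag=0):
    return f"{name}\t{flag}\tchrT\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"


@pytest.fixture()
def fixture_files(tmp_path):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(GTF)
    sam = tmp_path / "s1.sam"
    reads = [
        # three reads spanning intron [110, 210) with 10-base flanks
        sam_line("r1", 100, "10M100N10M"),
        sam_line("r2", 100, "10M100N10M"),
        sam_line("r3", 100, "10M100N10M"),
        # left flank of only 2 bases: filtered at min_anchor_overlap=8
        sam_line("r4", 108, "2M100N18M"),
        # junction bridging gene A and gene B: orphan
        sam_line("r5", 90, "20M200N20M", seq="A" * 40),
        # secondary alignment: skipped entirely
        sam_line("r6", 100, "10M100N10M", flag=0x100),
    ]
    sam.write_text(SAM_HEADER + "".join(reads))
    return {"gtf": gtf, "sam": sam}


class TestCountJunctions:
    def test_tally_and_filters(self, fixture_files):
        index = load_gtf(fixture_files["gtf"])
        table, juncs, orphans = count_junctions(
            {"s1": fixture_files["sam"]}, index, min_anchor_overlap=8)
        by_id = dict(zip(table.feature_ids, table.counts[:, 0]))
        assert by_id["chrT:110-210:+"] == 3  # r4 (2-base flank) excluded
        assert table.gene_map["chrT:110-210:+"] == "A"
        assert "chrT:110-310:+" in orphans  # spans two genes -> no gene
        # library size counts primary aligned reads only (r6 skipped)
        assert table.library_sizes[0] == 5

    def test_tally_conservation(self, toy_dataset):
        table, _juncs, _orph = count_junctions(
            toy_dataset["sam_paths"], toy_dataset["index"], toy_dataset["genome"])
        # every simulated read spans exactly one junction
        assert (table.counts.sum(axis=0) <= table.library_sizes).all()

    def test_recovers_simulated_tallies_exactly(self, toy_dataset):
        table, _juncs, _orph = count_junctions(
            toy_dataset["sam_paths"], toy_dataset["index"], toy_dataset["genome"])
        tallies = toy_dataset["tallies"]
        df = table.to_frame().loc[tallies.index, tallies.columns]
        assert (df.to_numpy() == tallies.to_numpy()).all()


class TestCountExons:
    def test_overlap_rules(self, fixture_files):
        index = load_gtf(fixture_files["gtf"])
        table = count_exons({"s1": fixture_files["sam"]}, index)
        by_id = dict(zip(table.feature_ids, table.counts[:, 0]))
        # spliced reads r1-r3 + r4 + r5 touch exon A:50-110; r5 also B
        assert by_id["A:50-110"] == 5
        assert by_id["A:210-250"] == 4  # r1..r4 right blocks
        assert by_id["B:260-380"] == 1  # r5 right block at [290,310)


# -- anchors and donor windows ----------------------------------------


class TestAnchorRegion:
    def test_plus_strand(self):
        a = anchor_region(Junction("c", 110, 210, "+"))
        assert (a.start, a.end, a.clipped) == (95, 110, False)

    def test_minus_strand(self):
        a = anchor_region(Junction("c", 110, 210, "-"))
        assert (a.start, a.end) == (210, 225)

    def test_clipped_at_chromosome_start(self):
        a = anchor_region(Junction("c", 7, 50, "+"))
        assert (a.start, a.end, a.clipped) == (0, 7, True)

    def test_no_overlap_with_intron(self):
        for strand in "+-":
            j = Junction("c", 100, 200, strand)
            a = anchor_region(j)
            assert a.end <= j.start or a.start >= j.end


class TestDonorWindow:
    def test_plus_strand(self):
        w = donor_window(Junction("c", 110, 210, "+"), flank=80)
        assert (w.start, w.end) == (30, 191)
        assert w.end - w.start == 161

    def test_minus_strand(self):
        # donor_pos = 209 for the minus-strand junction [110, 210)
        w = donor_window(Junction("c", 110, 210, "-"), flank=80)
        assert (w.start, w.end, w.strand) == (129, 290, "-")

    def test_minimal_flank(self):
        w = donor_window(Junction("c", 110, 210, "+"), flank=1)
        assert w.end - w.start == 3

    def test_clipping_flagged(self):
        w = donor_window(Junction("c", 10, 210, "+"), flank=80)
        assert w.clipped and w.start == 0


class TestStrandEquivariance:
    """Mirroring the genome (revcomp + flipped annotation) maps + onto -."""

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(100, 5000), st.integers(20, 500), st.integers(1000, 10_000))
    def test_anchor_and_window_mirror(self, start, ilen, extra):
        L = start + ilen + extra  # chromosome length
        j_fwd = Junction("c", start, start + ilen, "+")
        j_rev = Junction("c", L - (start + ilen), L - start, "-")
        a_f, a_r = anchor_region(j_fwd), anchor_region(j_rev)
        assert (a_r.start, a_r.end) == (L - a_f.end, L - a_f.start)
        w_f = donor_window(j_fwd, flank=80)
        w_r = donor_window(j_rev, flank=80)
        assert (w_r.start, w_r.end) == (L - w_f.end, L - w_f.start)


class TestStrandInference:
    """Without a unique gene assignment, strand comes from the intron's
    terminal dinucleotides (GT..AG forward, CT..AC reverse)."""

    def infer(self, intron_seq):
        from splicelab.genome import AnnotationIndex, Genome
        from splicelab.junctions import infer_junction_strand
        genome = Genome({"c": "AAAA" + intron_seq + "AAAA"})
        index = AnnotationIndex()
        index.finalize()
        return infer_junction_strand(genome, index, "c", 4, 4 + len(intron_seq))

    def test_canonical_forward(self):
        assert self.infer("GTAAGTCCAG") == ("+", None, False)

    def test_canonical_reverse(self):
        assert self.infer("CTTTGGTAAC") == ("-", None, False)

    def test_non_canonical_flagged_unoriented(self):
        strand, gene, unoriented = self.infer("TTTTTTTTTT")
        assert strand == "+" and unoriented


class TestJunctionType:
    def test_id_round_trip(self):
        j = Junction("chr2", 5, 99, "-")
        assert Junction.parse(j.id) == j

    def test_donor_acceptor_orientation(self):
        jp = Junction("c", 10, 20, "+")
        jm = Junction("c", 10, 20, "-")
        assert jp.donor_pos < jp.acceptor_pos
        assert jm.donor_pos > jm.acceptor_pos

    def test_empty_intron_rejected(self):
        with pytest.raises(ValueError):
            Junction("c", 10, 10, "+")
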