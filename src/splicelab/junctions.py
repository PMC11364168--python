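"""Splice-junction extraction and feature counting.

A junction is the intronic gap inferred from a spliced read alignment
(the ``N`` operation of its CIGAR). This module extracts junctions from
SAM/BAM alignments, counts junction/exon support per sample, and derives
the donor-anchored genomic regions used downstream:

* the *anchor* — the 15-nt exonic region immediately upstream (5', in
  transcript orientation) of the donor splice site, counted as its own
  feature to regain statistical power where junction reads are sparse;
* the *donor window* — the +/- ``flank`` nt region centred on the donor
  site (first intronic base), the sequence unit for RBP scanning and
  motif discovery.

Coordinates are 0-based half-open throughout; the junction interval
covers the intron only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .counts import CountTable
from .genome import AnnotationIndex, Genome, exon_feature_id

logger = logging.getLogger(__name__)

ANCHOR_LENGTH = 15
DEFAULT_MIN_ANCHOR_OVERLAP = 8
DEFAULT_FLANK = 80

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
#: reference-consuming CIGAR operations
_REF_OPS = set("MDN=X")
#: operations that count as aligned bases for anchor-overlap filtering
_ALIGNED_OPS = set("M=X")

SKIP_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


class CigarError(ValueError):
    pass


@dataclass(frozen=True)
class Junction:
    """A strand-aware intron interval.

    ``start`` is the first intronic base, ``end`` one past the last.
    The donor site is the intron's 5' end in transcript orientation:
    position ``start`` on ``+``, ``end - 1`` on ``-``. By convention the
    donor coordinate is the FIRST INTRONIC base.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"intron must be non-empty: [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor_pos(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, junction_id: str) -> "Junction":
        chrom, span, strand = junction_id.rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass(frozen=True)
class Anchor:
    """The 15-nt exonic region immediately 5' of a donor site."""

    junction_id: str
    chrom: str
    strand: str
    start: int
    end: int
    clipped: bool = False

    @property
    def id(self) -> str:
        return f"anchor:{self.junction_id}"


@dataclass(frozen=True)
class DonorWindow:
    junction_id: str
    chrom: str
    strand: str
    start: int
    end: int
    clipped: bool = False


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise CigarError(f"malformed CIGAR: {cigar!r}")
    return ops


def junctions_from_cigar(pos: int, cigar: str | list[tuple[int, str]]) -> list[tuple[int, int]]:
    """Intron intervals implied by the ``N`` operations of a CIGAR.

    *pos* is the 0-based reference start of the alignment. The reference
    cursor advances on M, D, N, = and X; I, S, H and P do not consume
    reference. Intervals are returned 5'->3' in reference order.
    """
    ops = parse_cigar(cigar) if isinstance(cigar, str) else cigar
    introns = []
    cursor = pos
    for length, op in ops:
        if op == "N":
            introns.append((cursor, cursor + length))
        if op in _REF_OPS:
            cursor += length
    return introns


def _junctions_with_flanks(cigartuples: list[tuple[int, int]], pos: int
                           ) -> list[tuple[int, int, int, int]]:
    """(start, end, left_flank, right_flank) per N gap, from pysam cigartuples.

    Flanks count aligned (M/=/X) bases between this gap and the adjacent
    gap (or read end)."""
    # pysam op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    cursor = pos
    aligned_since_gap = 0
    gaps = []  # (start, end, left_flank); right filled later
    for op, length in cigartuples:
        if op == 3:  # N
            gaps.append([cursor, cursor + length, aligned_since_gap, 0])
            aligned_since_gap = 0
            cursor += length
        elif op in (0, 7, 8):  # M, =, X
            aligned_since_gap += length
            cursor += length
        elif op == 2:  # D
            cursor += length
        # I, S, H, P: no reference, no aligned-base credit
    # right flank of gap i = aligned bases between gap i and gap i+1
    for i, gap in enumerate(gaps):
        if i + 1 < len(gaps):
            gap[3] = gaps[i + 1][2]
        else:
            gap[3] = aligned_since_gap
    return [tuple(g) for g in gaps]


def infer_junction_strand(genome: Genome | None, index: AnnotationIndex,
                          chrom: str, start: int, end: int
                          ) -> tuple[str, str | None, bool]:
    """Assign (strand, gene_id, unoriented_flag) for an intron interval.

    If both intron ends fall within exactly one gene's span, take that
    gene's strand. Otherwise fall back to the splice-site dinucleotides
    (GT..AG forward, CT..AC reverse); if neither matches, record '+' and
    flag the junction as unoriented.
    """
    genes_left = set(index.genes_containing(chrom, start))
    genes_right = set(index.genes_containing(chrom, end - 1))
    both = genes_left & genes_right
    if len(both) == 1:
        gene_id = next(iter(both))
        return index.genes[gene_id].strand, gene_id, False
    gene_id = None  # orphan: zero or ambiguous gene assignment
    if genome is not None and chrom in genome:
        seq = genome.sequences[chrom]
        if end <= len(seq) and end - start >= 4:
            first2, last2 = seq[start:start + 2], seq[end - 2:end]
            if first2 == "GT" and last2 == "AG":
                return "+", gene_id, False
            if first2 == "CT" and last2 == "AC":
                return "-", gene_id, False
    return "+", gene_id, True


def count_junctions(sam_paths: dict[str, str | Path], index: AnnotationIndex,
                    genome: Genome | None = None,
                    min_anchor_overlap: int = DEFAULT_MIN_ANCHOR_OVERLAP,
                    ) -> tuple[CountTable, list[Junction], list[str]]:
    """Count junction-supporting reads per sample.

    A read supports a junction only if it has at least
    *min_anchor_overlap* aligned (M/=/X) bases on both sides of the N
    gap. A junction is assigned to the unique gene whose span contains
    both intron ends; junctions with zero or multiple candidate genes
    are kept in the table but listed as orphans (no gene assignment).

    Returns (table, junction objects in table order, orphan junction ids).
    Library size per sample = number of primary aligned reads.
    """
    if min_anchor_overlap < 1:
        raise ValueError("min_anchor_overlap must be >= 1")
    sample_ids = list(sam_paths)
    per_sample: list[dict[tuple[str, int, int], int]] = []
    lib_sizes = []
    skipped = {"unmapped_or_secondary": 0, "low_anchor": 0}
    for sample in sample_ids:
        tallies: dict[tuple[str, int, int], int] = {}
        n_primary = 0
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as af:
            for read in af:
                if read.flag & SKIP_FLAGS:
                    skipped["unmapped_or_secondary"] += 1
                    continue
                n_primary += 1
                ct = read.cigartuples
                if ct is None:
                    continue
                for start, end, left, right in _junctions_with_flanks(ct, read.reference_start):
                    if left < min_anchor_overlap or right < min_anchor_overlap:
                        skipped["low_anchor"] += 1
                        continue
                    key = (read.reference_name, start, end)
                    tallies[key] = tallies.get(key, 0) + 1
        per_sample.append(tallies)
        lib_sizes.append(max(n_primary, 1))
    if skipped["unmapped_or_secondary"] or skipped["low_anchor"]:
        logger.info("count_junctions: skipped reads %s", skipped)

    keys = sorted({k for t in per_sample for k in t})
    junctions: list[Junction] = []
    gene_map: dict[str, str] = {}
    orphans: list[str] = []
    strand_cache: dict[tuple[str, int, int], tuple[str, str | None, bool]] = {}
    for key in keys:
        chrom, start, end = key
        strand, gene_id, unoriented = strand_cache.setdefault(
            key, infer_junction_strand(genome, index, chrom, start, end))
        j = Junction(chrom, start, end, strand)
        junctions.append(j)
        if gene_id is not None:
            gene_map[j.id] = gene_id
        else:
            orphans.append(j.id)
        if unoriented:
            logger.debug("junction %s unoriented (no gene, no canonical dinucleotide)", j.id)

    counts = np.zeros((len(keys), len(sample_ids)), dtype=np.int64)
    key_idx = {k: i for i, k in enumerate(keys)}
    for col, tallies in enumerate(per_sample):
        for k, n in tallies.items():
            counts[key_idx[k], col] = n
    table = CountTable([j.id for j in junctions], sample_ids, counts,
                       np.array(lib_sizes, dtype=float), gene_map=gene_map)
    return table, junctions, orphans


def _aligned_blocks(cigartuples: list[tuple[int, int]], pos: int) -> list[tuple[int, int]]:
    blocks = []
    cursor = pos
    block_start = None
    for op, length in cigartuples:
        if op in (0, 7, 8):
            if block_start is None:
                block_start = cursor
            cursor += length
        elif op in (2, 3):  # D or N end the aligned block (D kept simple: split)
            if block_start is not None:
                blocks.append((block_start, cursor))
                block_start = None
            cursor += length
    if block_start is not None:
        blocks.append((block_start, cursor))
    return blocks


def count_exons(sam_paths: dict[str, str | Path], index: AnnotationIndex
                ) -> CountTable:
    """Count reads overlapping each annotated exon by >= 1 aligned base.

    A spliced read may increment several exons. Exon intervals shared by
    multiple transcripts collapse to one feature per (gene, interval).
    """
    sample_ids = list(sam_paths)
    # collapse exons to (gene, interval) features
    features: list[tuple[str, str, int, int]] = []  # gene, chrom, start, end
    for gene_id, exons in sorted(index.gene_exons.items()):
        chrom = index.genes[gene_id].chrom
        for s, e in exons:
            features.append((gene_id, chrom, s, e))
    feat_ids = [exon_feature_id(g, s, e) for g, _c, s, e in features]
    # per-chromosome sorted exon arrays for overlap lookup
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, (_g, chrom, s, e) in enumerate(features):
        by_chrom.setdefault(chrom, []).append((s, e, i))
    for lst in by_chrom.values():
        lst.sort()

    counts = np.zeros((len(features), len(sample_ids)), dtype=np.int64)
    lib_sizes = []
    for col, sample in enumerate(sample_ids):
        n_primary = 0
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as af:
            for read in af:
                if read.flag & SKIP_FLAGS:
                    continue
                n_primary += 1
                ct = read.cigartuples
                if ct is None:
                    continue
                exon_hits: set[int] = set()
                chrom_exons = by_chrom.get(read.reference_name, [])
                for bs, be in _aligned_blocks(ct, read.reference_start):
                    for s, e, i in chrom_exons:
                        if s >= be:
                            break
                        if e > bs:
                            exon_hits.add(i)
                for i in exon_hits:
                    counts[i, col] += 1
        lib_sizes.append(max(n_primary, 1))
    gene_map = {fid: g for fid, (g, _c, _s, _e) in zip(feat_ids, features)}
    return CountTable(feat_ids, sample_ids, counts, np.array(lib_sizes, dtype=float),
                      gene_map=gene_map)


def count_regions(sam_paths: dict[str, str | Path],
                  regions: list[tuple[str, str, int, int]],
                  gene_map: dict[str, str] | None = None) -> CountTable:
    """Count reads overlapping arbitrary (id, chrom, start, end) regions.

    A read increments a region when any aligned block overlaps it by
    >= 1 base (used for anchor features). Library size = primary
    aligned reads.
    """
    sample_ids = list(sam_paths)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, (_rid, chrom, s, e) in enumerate(regions):
        by_chrom.setdefault(chrom, []).append((s, e, i))
    for lst in by_chrom.values():
        lst.sort()
    counts = np.zeros((len(regions), len(sample_ids)), dtype=np.int64)
    lib_sizes = []
    for col, sample in enumerate(sample_ids):
        n_primary = 0
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as af:
            for read in af:
                if read.flag & SKIP_FLAGS:
                    continue
                n_primary += 1
                ct = read.cigartuples
                if ct is None:
                    continue
                hits: set[int] = set()
                chrom_regions = by_chrom.get(read.reference_name, [])
                for bs, be in _aligned_blocks(ct, read.reference_start):
                    for s, e, i in chrom_regions:
                        if s >= be:
                            break
                        if e > bs:
                            hits.add(i)
                for i in hits:
                    counts[i, col] += 1
        lib_sizes.append(max(n_primary, 1))
    return CountTable([r[0] for r in regions], sample_ids, counts,
                      np.array(lib_sizes, dtype=float), gene_map=gene_map or {})


def anchor_region(j: Junction, chrom_length: int | None = None) -> Anchor:
    """The 15-nt exonic anchor immediately upstream of the donor site.

    On ``+`` this is ``[start-15, start)``; on ``-`` it is
    ``[end, end+15)``. Intervals extending past the chromosome ends are
    clipped and flagged, never fatal.
    """
    if j.strand == "+":
        start, end = j.start - ANCHOR_LENGTH, j.start
    else:
        start, end = j.end, j.end + ANCHOR_LENGTH
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return Anchor(j.id, j.chrom, j.strand, start, end, clipped)


def donor_window(j: Junction, flank: int = DEFAULT_FLANK,
                 chrom_length: int | None = None) -> DonorWindow:
    """The 2*flank+1 nt window centred on the donor site (first intronic base).

    Returned with the junction's strand so that ``fetch_sequence`` on
    the interval yields the transcript-oriented sequence with the donor
    base at the centre. Windows truncated at chromosome ends are flagged
    clipped.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    start = j.donor_pos - flank
    end = j.donor_pos + flank + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return DonorWindow(j.id, j.chrom, j.strand, start, end, clipped)


# -- writers ----------------------------------------------------------

def write_junction_table(path: str | Path, table: CountTable,
                         junctions: list[Junction]) -> None:
    with open(path, "w") as fh:
        fh.write("junction_id\tchrom\tstart\tend\tstrand\tgene_id\t"
                 + "\t".join(table.sample_ids) + "\n")
        for i, j in enumerate(junctions):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{j.id}\t{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t"
                     f"{table.gene_map.get(j.id, '')}\t{counts}\n")


def write_bed(path: str | Path, records: list[tuple[str, int, int, str, str]]) -> None:
    """Write (chrom, start, end, name, strand) records as 6-column BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
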