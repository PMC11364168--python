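"""Genome and annotation handling.

Loads a genome assembly (FASTA) and a gene annotation (GTF, Ensembl
attribute dialect) into memory, and provides strand-aware sequence
retrieval plus positional feature lookup (which genes/exons overlap a
genomic position).

All internal coordinates are 0-based half-open; conversion from the
GTF's 1-based inclusive convention happens only inside :func:`load_gtf`.
"""

from __future__ import annotations

import logging
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: width of the fixed interval-index bins, in bases
BIN_SIZE = 16384


class GenomeError(ValueError):
    """Raised for malformed genome or annotation input."""


@dataclass
class Genome:
    """In-memory genome: chromosome name -> uppercase sequence (A,C,G,T,N)."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA into a :class:`Genome`.

    Record keys are the first whitespace-separated token of the header.
    Sequences are uppercased on load. Duplicate chromosome names and
    empty records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        seq = str(record.seq).upper()
        if not seq:
            raise GenomeError(f"empty FASTA record: {name!r}")
        if name in sequences:
            raise GenomeError(f"duplicate chromosome name: {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise GenomeError(f"invalid characters in {name!r}: {sorted(bad)}")
        sequences[name] = seq
    if not sequences:
        raise GenomeError(f"no FASTA records in {path}")
    return Genome(sequences)


def fetch_sequence(genome: Genome, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Return the sequence of ``[start, end)`` on *chrom*.

    ``+`` returns the forward slice; ``-`` returns its reverse
    complement (i.e. the transcribed-strand sequence of a minus-strand
    feature). Out-of-bounds coordinates raise rather than clip.
    """
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome.sequences[chrom]
    if not (0 <= start <= end <= len(seq)):
        raise IndexError(
            f"interval [{start},{end}) out of bounds for {chrom} (length {len(seq)})"
        )
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    piece = seq[start:end]
    return reverse_complement(piece) if strand == "-" else piece


@dataclass
class GeneRecord:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    #: ordered (by genomic start) list of exon intervals, 0-based half-open
    exons: list[tuple[int, int]] = field(default_factory=list)


def exon_feature_id(gene_id: str, start: int, end: int) -> str:
    return f"{gene_id}:{start}-{end}"


class AnnotationIndex:
    """Indexed gene/transcript/exon annotation.

    Genes are registered in fixed-width bins per chromosome so that
    point queries touch only the genes whose span overlaps the query
    bin. A brute-force scan (``features_at_bruteforce``) is kept as the
    reference implementation.
    """

    def __init__(self) -> None:
        self.genes: dict[str, GeneRecord] = {}
        self.transcripts: dict[str, TranscriptRecord] = {}
        # gene_id -> sorted unique exon intervals
        self.gene_exons: dict[str, list[tuple[int, int]]] = {}
        self._bins: dict[tuple[str, int], list[str]] = {}

    # -- construction -------------------------------------------------

    def add_gene(self, gene: GeneRecord) -> None:
        if gene.gene_id in self.genes:
            existing = self.genes[gene.gene_id]
            if existing.chrom != gene.chrom:
                raise GenomeError(
                    f"gene_id {gene.gene_id!r} appears on both "
                    f"{existing.chrom} and {gene.chrom}"
                )
            existing.start = min(existing.start, gene.start)
            existing.end = max(existing.end, gene.end)
            return
        self.genes[gene.gene_id] = gene
        self.gene_exons.setdefault(gene.gene_id, [])

    def add_exon(self, transcript_id: str, gene_id: str, chrom: str, strand: str,
                 start: int, end: int) -> None:
        tr = self.transcripts.get(transcript_id)
        if tr is None:
            tr = TranscriptRecord(transcript_id, gene_id)
            self.transcripts[transcript_id] = tr
        insort(tr.exons, (start, end))
        exons = self.gene_exons.setdefault(gene_id, [])
        if (start, end) not in exons:
            insort(exons, (start, end))
        if gene_id not in self.genes:
            self.add_gene(GeneRecord(gene_id, gene_id, chrom, strand, start, end))
        else:
            g = self.genes[gene_id]
            g.start = min(g.start, start)
            g.end = max(g.end, end)

    def finalize(self) -> None:
        """Build the bin index; call after all records are added."""
        self._bins.clear()
        for gene in self.genes.values():
            for b in range(gene.start // BIN_SIZE, (max(gene.end - 1, gene.start)) // BIN_SIZE + 1):
                self._bins.setdefault((gene.chrom, b), []).append(gene.gene_id)
        for ids in self._bins.values():
            ids.sort()

    # -- queries ------------------------------------------------------

    def features_at(self, chrom: str, pos: int) -> list[tuple[str, list[str]]]:
        """Genes whose span contains *pos*, each with the exon ids containing it.

        An empty exon list means the position is intronic for that gene.
        Results are ordered by gene_id; an unknown chromosome yields [].
        """
        hits = []
        for gene_id in self._bins.get((chrom, pos // BIN_SIZE), ()):
            gene = self.genes[gene_id]
            if gene.start <= pos < gene.end:
                exon_ids = [
                    exon_feature_id(gene_id, s, e)
                    for s, e in self.gene_exons.get(gene_id, [])
                    if s <= pos < e
                ]
                hits.append((gene_id, exon_ids))
        return hits

    def features_at_bruteforce(self, chrom: str, pos: int) -> list[tuple[str, list[str]]]:
        """Linear-scan reference for :meth:`features_at`."""
        hits = []
        for gene_id in sorted(self.genes):
            gene = self.genes[gene_id]
            if gene.chrom == chrom and gene.start <= pos < gene.end:
                exon_ids = [
                    exon_feature_id(gene_id, s, e)
                    for s, e in self.gene_exons.get(gene_id, [])
                    if s <= pos < e
                ]
                hits.append((gene_id, exon_ids))
        return hits

    def genes_containing(self, chrom: str, pos: int) -> list[str]:
        """gene_ids whose span contains *pos* (sorted)."""
        return [g for g, _ in self.features_at(chrom, pos)]


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gtf(path: str | Path) -> AnnotationIndex:
    """Parse a GTF (Ensembl attribute dialect) into an :class:`AnnotationIndex`.

    Only ``gene``, ``transcript`` and ``exon`` feature lines are used;
    other feature types are skipped. GTF 1-based inclusive coordinates
    become 0-based half-open. Records with a strand outside {+,-} or an
    exon without a transcript_id are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    index = AnnotationIndex()
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("GTF line %d: fewer than 9 fields, skipped", lineno)
                n_skipped += 1
                continue
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr_text = fields[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            if strand not in ("+", "-"):
                logger.warning("GTF line %d: strand %r not in {+,-}, record skipped",
                               lineno, strand)
                n_skipped += 1
                continue
            start = int(start1) - 1  # 1-based inclusive -> 0-based half-open
            end = int(end1)
            if start >= end:
                logger.warning("GTF line %d: empty/inverted interval, skipped", lineno)
                n_skipped += 1
                continue
            attrs = _parse_gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                logger.warning("GTF line %d: missing gene_id, skipped", lineno)
                n_skipped += 1
                continue
            if feature == "gene":
                index.add_gene(GeneRecord(
                    gene_id, attrs.get("gene_name", gene_id), chrom, strand, start, end))
            else:
                transcript_id = attrs.get("transcript_id")
                if transcript_id is None:
                    logger.warning("GTF line %d: %s without transcript_id, skipped",
                                   lineno, feature)
                    n_skipped += 1
                    continue
                if feature == "transcript":
                    if transcript_id not in index.transcripts:
                        index.transcripts[transcript_id] = TranscriptRecord(
                            transcript_id, gene_id)
                else:
                    index.add_exon(transcript_id, gene_id, chrom, strand, start, end)
    if n_skipped:
        logger.warning("load_gtf: %d records skipped", n_skipped)
    index.finalize()
    return index
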