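"""Synthetic data generation for every pipeline stage.

Emulates the inputs of a two-condition short-read splicing experiment
at desk scale: a multi-gene toy genome with multi-exon transcripts
(introns canonical GT..AG on the transcribed strand, genes alternating
strands), spliced SAM alignments with M-N-M CIGARs at controllable
per-junction depth, count tables with planted within-gene usage shifts,
and donor-window sequence sets with a motif planted near the donor site
in one class.

Every generator is a pure function of its :class:`SimConfig`: the same
seed yields byte-identical files. Generators write real FASTA/GTF/SAM
files so the reader code paths are exercised, not bypassed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountTable

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    ``depth`` is the expected read count per junction per sample;
    ``usage_shift`` the planted change in the first junction's usage
    proportion (e.g. 0.5 -> 0.9 for a two-junction gene at 0.4);
    ``dispersion`` the negative-binomial dispersion of gene totals.
    """

    seed: int
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_len: tuple[int, int] = (80, 160)
    intron_len: tuple[int, int] = (200, 400)
    n_samples: int = 3          # per condition
    depth: float = 200.0        # expected reads per junction per sample
    usage_shift: float = 0.4
    dispersion: float = 0.05
    n_planted: int | None = None  # default: n_genes // 10
    motif: str = "AGAGTAA"
    plant_rate_target: float = 0.6
    plant_rate_background: float = 0.05
    read_flank: int = 30        # aligned bases on each side of the junction
    intergenic_gap: int = 300
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for prob in (self.plant_rate_target, self.plant_rate_background):
            if not 0 <= prob <= 1:
                raise ValueError("plant rates must be in [0, 1]")
        if not 0 <= self.usage_shift <= 0.45:
            raise ValueError("usage_shift must be in [0, 0.45]")
        if self.exons_per_gene < 2:
            raise ValueError("need >= 2 exons per gene")
        if min(self.exon_len) <= self.read_flank:
            raise ValueError("exon length must exceed read_flank")
        if min(self.intron_len) < 4 or min(self.exon_len) < 1:
            raise ValueError("lengths must be positive (introns >= 4 nt)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def junctions_per_gene(self) -> int:
        return self.exons_per_gene - 1

    @property
    def planted_count(self) -> int:
        return self.n_genes // 10 if self.n_planted is None else self.n_planted


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent child streams per generator stage, all keyed on cfg.seed
    return np.random.default_rng([cfg.seed, stream])


def make_toy_genome(cfg: SimConfig, out_dir: str | Path
                    ) -> tuple[Path, Path, pd.DataFrame]:
    """Write genome.fa + annotation.gtf; return their paths and the junction truth.

    Genes alternate strands along one chromosome. Every intron carries
    the canonical splice dinucleotides on its transcribed strand (GT at
    the donor, AG at the acceptor), so strand inference from sequence is
    exercised. The truth table lists every junction with its gene,
    strand, intron interval, donor position and planted role: junction 0
    of each planted gene is "planted", its gene-mates are "sibling"
    (their usage shifts complementarily), all others "null".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg, 1)

    planted_genes = set(rng.choice(cfg.n_genes, size=cfg.planted_count,
                                   replace=False)) if cfg.planted_count else set()

    seq_parts: list[str] = []
    cursor = 0
    gtf_lines: list[str] = []
    truth_rows = []
    for gi in range(cfg.n_genes):
        gid = f"G{gi:05d}"
        tid = f"T{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        gap = rng.integers(cfg.intergenic_gap // 2, cfg.intergenic_gap + 1)
        seq_parts.append("".join(rng.choice(BASES, size=gap)))
        cursor += gap
        exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1,
                                 size=cfg.exons_per_gene)
        intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1,
                                   size=cfg.junctions_per_gene)
        gene_start = cursor
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        for k in range(cfg.exons_per_gene):
            elen = int(exon_lens[k])
            seq_parts.append("".join(rng.choice(BASES, size=elen)))
            exons.append((cursor, cursor + elen))
            cursor += elen
            if k < cfg.junctions_per_gene:
                ilen = int(intron_lens[k])
                intron = "".join(rng.choice(BASES, size=ilen))
                if strand == "+":
                    intron = "GT" + intron[2:-2] + "AG"
                else:
                    intron = "CT" + intron[2:-2] + "AC"
                seq_parts.append(intron)
                introns.append((cursor, cursor + ilen))
                cursor += ilen
        gene_end = cursor
        gtf_attrs = f'gene_id "{gid}"; gene_name "{gid}";'
        gtf_lines.append("\t".join([cfg.chrom_name, "sim", "gene",
                                    str(gene_start + 1), str(gene_end), ".",
                                    strand, ".", gtf_attrs]))
        tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        gtf_lines.append("\t".join([cfg.chrom_name, "sim", "transcript",
                                    str(gene_start + 1), str(gene_end), ".",
                                    strand, ".", tattrs]))
        for (es, ee) in exons:
            gtf_lines.append("\t".join([cfg.chrom_name, "sim", "exon",
                                        str(es + 1), str(ee), ".", strand, ".",
                                        tattrs]))
        # junction order in transcript orientation: genomic order on +,
        # reversed on -
        ordered = introns if strand == "+" else introns[::-1]
        for jx, (s, e) in enumerate(ordered):
            donor = s if strand == "+" else e - 1
            if gi in planted_genes:
                role = "planted" if jx == 0 else "sibling"
            else:
                role = "null"
            truth_rows.append({
                "junction_id": f"{cfg.chrom_name}:{s}-{e}:{strand}",
                "gene_id": gid, "chrom": cfg.chrom_name, "strand": strand,
                "start": s, "end": e, "donor_pos": donor,
                "junction_index": jx, "role": role,
            })

    genome_path = out_dir / "genome.fa"
    seq = "".join(seq_parts)
    with open(genome_path, "w") as fh:
        fh.write(f">{cfg.chrom_name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    gtf_path = out_dir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth_junctions.tsv", sep="\t", index=False)
    return genome_path, gtf_path, truth


def _usage_proportions(cfg: SimConfig, n_junc: int, planted: bool, condition: str
                       ) -> np.ndarray:
    p = np.full(n_junc, 1.0 / n_junc)
    if planted and condition == "test" and n_junc >= 2:
        p0 = 1.0 / n_junc + cfg.usage_shift
        p = np.full(n_junc, (1.0 - p0) / (n_junc - 1))
        p[0] = p0
    return p


def _gene_total(rng: np.random.Generator, mean: float, phi: float) -> int:
    if phi <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return int(rng.poisson(lam))


def simulate_spliced_reads(cfg: SimConfig, genome_seq: str, truth: pd.DataFrame,
                           out_dir: str | Path
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write one SAM per sample with spliced reads over the truth junctions.

    Reads have ``fMiNfM`` CIGARs with ``f = read_flank`` aligned bases
    on each side of the intron. Per-sample junction tallies follow the
    gene-total / within-gene-usage model of :func:`simulate_count_pair`.
    Returns (sample sheet with sample_id/path/condition, realized
    per-sample tallies per junction).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg, 2)
    f = cfg.read_flank
    qual = "I" * (2 * f)

    genes = truth.groupby("gene_id", sort=True)
    samples = [(f"{cond}{i + 1}", cond)
               for cond in ("control", "test") for i in range(cfg.n_samples)]
    sheet_rows = []
    tally_rows: dict[str, dict[str, int]] = {jid: {} for jid in truth["junction_id"]}

    handles = {}
    header = ["@HD\tVN:1.6\tSO:unsorted",
              f"@SQ\tSN:{cfg.chrom_name}\tLN:{len(genome_seq)}"]
    for sample_id, cond in samples:
        path = out_dir / f"{sample_id}.sam"
        fh = open(path, "w")
        fh.write("\n".join(header) + "\n")
        handles[sample_id] = fh
        sheet_rows.append({"sample_id": sample_id, "path": str(path),
                           "condition": cond})

    for gid, jdf in genes:
        jdf = jdf.sort_values("junction_index")
        n_junc = len(jdf)
        planted = (jdf["role"] == "planted").any()
        starts = jdf["start"].to_numpy()
        ends = jdf["end"].to_numpy()
        jids = jdf["junction_id"].to_list()
        # pre-render one SAM line template per junction
        templates = []
        for s, e in zip(starts, ends):
            read_seq = genome_seq[s - f:s] + genome_seq[e:e + f]
            cigar = f"{f}M{e - s}N{f}M"
            templates.append(
                f"\t0\t{cfg.chrom_name}\t{s - f + 1}\t255\t{cigar}\t*\t0\t0\t"
                f"{read_seq}\t{qual}\n")
        for sample_id, cond in samples:
            total = _gene_total(rng, cfg.depth * n_junc, cfg.dispersion)
            props = _usage_proportions(cfg, n_junc, planted, cond)
            counts = rng.multinomial(total, props)
            fh = handles[sample_id]
            for jx, c in enumerate(counts):
                tally_rows[jids[jx]][sample_id] = int(c)
                tpl = templates[jx]
                jid_tag = f"{gid}.{jx}"
                for r in range(c):
                    fh.write(f"rd_{sample_id}_{jid_tag}_{r}{tpl}")

    for fh in handles.values():
        fh.close()
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    tallies = pd.DataFrame.from_dict(tally_rows, orient="index").fillna(0).astype(int)
    tallies.index.name = "junction_id"
    tallies.to_csv(out_dir / "truth_tallies.tsv", sep="\t")
    return sheet, tallies


def simulate_count_pair(cfg: SimConfig) -> tuple[CountTable, dict[str, str],
                                                 pd.DataFrame]:
    """Two-condition junction count table with planted usage shifts.

    Per gene and sample the total count is negative-binomial (mean
    ``depth * n_junctions``, dispersion ``dispersion``); junction counts
    are multinomial within the gene, with the planted genes' first
    junction shifted by ``usage_shift`` in the test condition. Returns
    (table, feature -> gene map, truth with one row per feature and its
    role/true shift).
    """
    rng = _rng(cfg, 3)
    n_junc = cfg.junctions_per_gene
    planted_genes = set(rng.choice(cfg.n_genes, size=cfg.planted_count,
                                   replace=False)) if cfg.planted_count else set()
    samples = [(f"{cond}{i + 1}", cond)
               for cond in ("control", "test") for i in range(cfg.n_samples)]

    feature_ids, gene_map, truth_rows = [], {}, []
    counts = np.zeros((cfg.n_genes * n_junc, len(samples)), dtype=np.int64)
    row = 0
    for gi in range(cfg.n_genes):
        gid = f"G{gi:05d}"
        planted = gi in planted_genes
        for col, (sample_id, cond) in enumerate(samples):
            total = _gene_total(rng, cfg.depth * n_junc, cfg.dispersion)
            props = _usage_proportions(cfg, n_junc, planted, cond)
            counts[row:row + n_junc, col] = rng.multinomial(total, props)
        for jx in range(n_junc):
            fid = f"{gid}:J{jx}"
            feature_ids.append(fid)
            gene_map[fid] = gid
            role = ("planted" if planted and jx == 0
                    else "sibling" if planted else "null")
            truth_rows.append({"feature_id": fid, "gene_id": gid, "role": role,
                               "true_shift": cfg.usage_shift if role == "planted"
                               else 0.0})
        row += n_junc

    libs = counts.sum(axis=0).astype(float)
    libs[libs == 0] = 1.0
    table = CountTable(feature_ids, [s for s, _ in samples], counts, libs,
                       gene_map=gene_map)
    return table, gene_map, pd.DataFrame(truth_rows)


def plant_motif(sequences: dict[str, list[str]], cfg: SimConfig,
                target_class: str, flank: int | None = None,
                ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Plant ``cfg.motif`` near the donor site of a fraction of sequences.

    Target-class sequences receive the motif with probability
    ``plant_rate_target``, every other class with
    ``plant_rate_background``. The insertion replaces a substring at a
    position drawn uniformly over window starts overlapping offsets
    [-10, +10] of the donor site (sequence centre unless *flank* is
    given). Returns the mutated sets and a truth table of insertions.
    """
    rng = _rng(cfg, 4)
    motif = cfg.motif
    out: dict[str, list[str]] = {}
    rows = []
    for cls, seqs in sequences.items():
        rate = cfg.plant_rate_target if cls == target_class else cfg.plant_rate_background
        mutated = []
        for i, seq in enumerate(seqs):
            if len(motif) >= len(seq):
                raise ValueError("motif must be shorter than the sequences")
            centre = flank if flank is not None else (len(seq) - 1) // 2
            lo = max(0, centre - 10 - len(motif) + 1)
            hi = min(len(seq) - len(motif), centre + 10)
            if rng.random() < rate:
                pos = int(rng.integers(lo, hi + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
                rows.append({"class": cls, "index": i, "position": pos,
                             "offset": pos - centre})
            mutated.append(seq)
        out[cls] = mutated
    return out, pd.DataFrame(rows, columns=["class", "index", "position", "offset"])


def kmer_frequency(sequences: list[str], kmer: str) -> float:
    """Fraction of sequences containing *kmer* at least once."""
    if not sequences:
        return 0.0
    return sum(kmer in s for s in sequences) / len(sequences)
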