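"""Donor splice-site classification and per-class sequence emission.

Two schemes partition donor sites of tested junctions into named
classes, each carrying its donor-window sequence for downstream RBP
scanning and motif discovery:

* ``splice_site`` — enhanced (significant, logFC above the enhanced
  cut-off), repressed (significant, logFC below the repressed cut-off)
  and control (clearly unregulated: FDR above the control cut-off).
* ``donjuan`` — included / skipped / control, driven by a combined
  junction + anchor logFC signal among significant junctions. Anchors
  add power where junction read support is thin; how the two signals
  combine ("mean", "min" = the signal closer to zero, or "anchor_only")
  is an explicit strategy parameter.

Junctions that are significant but below the effect cut-offs, or with
FDR between the significance and control cut-offs, land in a residual
"unassigned" table rather than being silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diffuse import Thresholds
from .genome import Genome, fetch_sequence
from .junctions import Junction, donor_window

logger = logging.getLogger(__name__)

SPLICE_SITE_CLASSES = ("enhanced", "repressed", "control")
DONJUAN_CLASSES = ("included", "skipped", "control")
COMBINE_STRATEGIES = ("mean", "min", "anchor_only")


@dataclass
class SiteRecord:
    junction_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    junction_lfc: float
    fdr: float
    anchor_lfc: float | None = None
    combined_lfc: float | None = None


@dataclass
class ClassedSiteSets:
    scheme: str  # "splice_site" | "donjuan"
    classes: dict[str, list[SiteRecord]]
    thresholds: Thresholds
    flank: int
    unassigned: list[str] = field(default_factory=list)
    n_clipped: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, records in self.classes.items():
            for r in records:
                if r.junction_id in seen:
                    raise ValueError(
                        f"junction {r.junction_id} in both {seen[r.junction_id]} "
                        f"and {name}")
                seen[r.junction_id] = name
                if len(r.sequence) != r.end - r.start:
                    raise ValueError(
                        f"{r.junction_id}: sequence length {len(r.sequence)} != "
                        f"interval length {r.end - r.start}")

    def sequences(self, class_name: str) -> list[str]:
        return [r.sequence for r in self.classes.get(class_name, [])]


def _window_record(j: Junction, genome: Genome, flank: int,
                   junction_lfc: float, fdr: float) -> SiteRecord | None:
    """Donor-window sequence for a junction; None when the window is clipped."""
    w = donor_window(j, flank=flank, chrom_length=len(genome.sequences[j.chrom]))
    if w.clipped:
        return None
    seq = fetch_sequence(genome, w.chrom, w.start, w.end, w.strand)
    return SiteRecord(j.id, w.chrom, w.start, w.end, w.strand, seq,
                      junction_lfc, fdr)


def classify_splice_sites(junction_results: pd.DataFrame,
                          junctions: dict[str, Junction], genome: Genome,
                          t: Thresholds | None = None,
                          flank: int = 80) -> ClassedSiteSets:
    """Partition donor sites into enhanced / repressed / control.

    enhanced: fdr < fdr_sig and logFC > site_enh_lfc;
    repressed: fdr < fdr_sig and logFC < site_rep_lfc;
    control:   fdr > fdr_control.
    Everything else is recorded as unassigned. Sites whose donor window
    runs off the chromosome are dropped from their class and counted.
    """
    t = t or Thresholds()
    classes: dict[str, list[SiteRecord]] = {name: [] for name in SPLICE_SITE_CLASSES}
    unassigned: list[str] = []
    n_clipped = 0
    for row in junction_results.itertuples(index=False):
        jid, lfc, fdr = row.feature_id, row.logFC, row.fdr
        if jid not in junctions:
            continue
        if fdr < t.fdr_sig and lfc > t.site_enh_lfc:
            label = "enhanced"
        elif fdr < t.fdr_sig and lfc < t.site_rep_lfc:
            label = "repressed"
        elif fdr > t.fdr_control:
            label = "control"
        else:
            unassigned.append(jid)
            continue
        rec = _window_record(junctions[jid], genome, flank, lfc, fdr)
        if rec is None:
            n_clipped += 1
            continue
        classes[label].append(rec)
    for records in classes.values():
        records.sort(key=lambda r: r.junction_id)
    return ClassedSiteSets("splice_site", classes, t, flank,
                           unassigned=unassigned, n_clipped=n_clipped)


def combine_lfc(junction_lfc: float, anchor_lfc: float | None,
                strategy: str = "mean") -> float:
    """Combine the junction and anchor logFC signals for DonJuAn.

    "mean": arithmetic mean; "min": the signal of smaller magnitude
    (conservative); "anchor_only": the anchor signal. A missing anchor
    value always falls back to the junction logFC.
    """
    if anchor_lfc is None:
        return junction_lfc
    if strategy == "mean":
        return (junction_lfc + anchor_lfc) / 2.0
    if strategy == "min":
        return min(junction_lfc, anchor_lfc, key=abs)
    if strategy == "anchor_only":
        return anchor_lfc
    raise ValueError(f"unknown combine strategy {strategy!r}; "
                     f"choose from {COMBINE_STRATEGIES}")


def donjuan_classify(junction_results: pd.DataFrame,
                     anchor_results: pd.DataFrame,
                     junctions: dict[str, Junction], genome: Genome,
                     t: Thresholds | None = None, flank: int = 80,
                     combine: str = "mean") -> ClassedSiteSets:
    """DonJuAn classification: included / skipped / control donor sites.

    Candidates are junctions with junction fdr < fdr_sig. The combined
    junction+anchor logFC decides inclusion (> donjuan_inc_lfc) versus
    skipping (< donjuan_skip_lfc); junctions with fdr > fdr_control are
    controls regardless of effect size. Anchor results join on
    junction_id; junctions without one fall back to the junction logFC
    (flagged via combined == junction value, counted in the log).
    """
    t = t or Thresholds()
    anchor_lfc_map = anchor_results.set_index("feature_id")["logFC"].to_dict()
    classes: dict[str, list[SiteRecord]] = {name: [] for name in DONJUAN_CLASSES}
    unassigned: list[str] = []
    n_clipped = 0
    n_no_anchor = 0
    for row in junction_results.itertuples(index=False):
        jid, lfc, fdr = row.feature_id, row.logFC, row.fdr
        if jid not in junctions:
            continue
        a_lfc = anchor_lfc_map.get(f"anchor:{jid}", anchor_lfc_map.get(jid))
        if a_lfc is None:
            n_no_anchor += 1
        comb = combine_lfc(lfc, a_lfc, strategy=combine)
        if fdr < t.fdr_sig and comb > t.donjuan_inc_lfc:
            label = "included"
        elif fdr < t.fdr_sig and comb < t.donjuan_skip_lfc:
            label = "skipped"
        elif fdr > t.fdr_control:
            label = "control"
        else:
            unassigned.append(jid)
            continue
        rec = _window_record(junctions[jid], genome, flank, lfc, fdr)
        if rec is None:
            n_clipped += 1
            continue
        rec.anchor_lfc = a_lfc
        rec.combined_lfc = comb
        classes[label].append(rec)
    if n_no_anchor:
        logger.warning("donjuan_classify: %d junctions without anchor result; "
                       "junction logFC used alone", n_no_anchor)
    for records in classes.values():
        records.sort(key=lambda r: r.junction_id)
    return ClassedSiteSets("donjuan", classes, t, flank,
                           unassigned=unassigned, n_clipped=n_clipped)


def emit_class_fasta(sets: ClassedSiteSets, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per class; record order deterministic by junction_id.

    Headers are ``junction_id|class|chrom:start-end:strand`` so they
    parse back to coordinates. Empty classes produce empty files with a
    warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, records in sets.classes.items():
        path = out_dir / f"{sets.scheme}_{name}.fa"
        with open(path, "w") as fh:
            for r in sorted(records, key=lambda r: r.junction_id):
                fh.write(f">{r.junction_id}|{name}|{r.chrom}:{r.start}-{r.end}:{r.strand}\n")
                fh.write(r.sequence.upper() + "\n")
        if not records:
            logger.warning("emit_class_fasta: class %r is empty", name)
        paths[name] = path
    return paths


def write_class_table(path: str | Path, sets: ClassedSiteSets) -> None:
    rows = []
    for name, records in sets.classes.items():
        for r in records:
            rows.append({
                "junction_id": r.junction_id, "class": name, "scheme": sets.scheme,
                "junction_lfc": r.junction_lfc,
                "anchor_lfc": "" if r.anchor_lfc is None else r.anchor_lfc,
                "combined_lfc": "" if r.combined_lfc is None else r.combined_lfc,
                "fdr": r.fdr,
            })
    for jid in sets.unassigned:
        rows.append({"junction_id": jid, "class": "unassigned",
                     "scheme": sets.scheme, "junction_lfc": "", "anchor_lfc": "",
                     "combined_lfc": "", "fdr": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
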