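"""Pipeline orchestration: configuration, staged execution, manifest.

Stages run in dependency order and write plain TSV artifacts into the
output directory; a manifest records every stage with its outputs and
wall time. Re-running with unchanged inputs overwrites the same files
deterministically.
"""

from __future__ import annotations

import configparser
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import diffuse, judge, junctions as jmod, scanrbp, siteclass
from .counts import CountTable
from .diffuse import Comparison, Thresholds
from .genome import Genome, load_fasta, load_gtf

logger = logging.getLogger(__name__)

STAGE_ORDER = ["junctions", "exons", "anchors", "diff", "judge", "classes",
               "scanrbp", "report"]
STAGE_DEPS = {
    "junctions": [],
    "exons": [],
    "anchors": ["junctions"],
    "diff": ["junctions", "anchors"],
    "judge": ["diff"],
    "classes": ["diff"],
    "scanrbp": ["classes"],
    "report": [],
}


@dataclass
class RunConfig:
    genome_fasta: Path
    gtf: Path
    samples: pd.DataFrame          # sample_id, path, condition
    comparisons: list[Comparison]
    out_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    pwm_path: Path | None = None
    seed: int = 0
    flank: int = 80
    min_anchor_overlap: int = jmod.DEFAULT_MIN_ANCHOR_OVERLAP
    scan_n_iter: int = 10_000

    def validate(self) -> None:
        for p in [self.genome_fasta, self.gtf] + list(self.samples["path"]):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        known = set(self.samples["sample_id"])
        for c in self.comparisons:
            missing = (set(c.test) | set(c.control)) - known
            if missing:
                raise ValueError(f"comparison {c.name!r} references unknown "
                                 f"samples {sorted(missing)}")


def load_run_config(config_dir: str | Path, out_dir: str | Path,
                    seed: int = 0) -> RunConfig:
    """Assemble a RunConfig from a configuration directory.

    Expected files: ``samples.tsv`` (sample_id, path, condition),
    ``comparisons.tsv`` (name, test_condition, control_condition),
    optional ``thresholds.ini`` ([thresholds] section) and
    ``paths.ini`` ([paths] genome/gtf/pwms).
    """
    config_dir = Path(config_dir)
    samples = pd.read_csv(config_dir / "samples.tsv", sep="\t")
    comp_df = pd.read_csv(config_dir / "comparisons.tsv", sep="\t")
    comparisons = []
    for row in comp_df.itertuples(index=False):
        test = tuple(samples.loc[samples["condition"] == row.test_condition,
                                 "sample_id"])
        control = tuple(samples.loc[samples["condition"] == row.control_condition,
                                    "sample_id"])
        comparisons.append(Comparison(row.name, test, control))
    thresholds = Thresholds()
    ini = config_dir / "thresholds.ini"
    if ini.exists():
        parser = configparser.ConfigParser()
        parser.read(ini)
        if parser.has_section("thresholds"):
            valid = {f.name for f in dc_fields(Thresholds)}
            kwargs = {k: float(v) for k, v in parser["thresholds"].items()
                      if k in valid}
            thresholds = Thresholds(**kwargs)
    paths = configparser.ConfigParser()
    paths.read(config_dir / "paths.ini")
    pwm = paths.get("paths", "pwms", fallback=None)
    return RunConfig(
        genome_fasta=Path(paths.get("paths", "genome",
                                    fallback=config_dir / "genome.fa")),
        gtf=Path(paths.get("paths", "gtf", fallback=config_dir / "annotation.gtf")),
        samples=samples,
        comparisons=comparisons,
        out_dir=Path(out_dir),
        thresholds=thresholds,
        pwm_path=Path(pwm) if pwm else None,
        seed=seed,
    )


class PipelineError(RuntimeError):
    pass


def run_pipeline(cfg: RunConfig, stages: set[str] | None = None) -> pd.DataFrame:
    """Execute the requested stages in dependency order; return the manifest.

    A requested stage whose upstream artifacts are neither requested nor
    already on disk raises a :class:`PipelineError` naming the missing
    stage.
    """
    cfg.validate()
    stages = set(stages or STAGE_ORDER)
    unknown = stages - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sam_paths = dict(zip(cfg.samples["sample_id"], cfg.samples["path"]))
    genome = load_fasta(cfg.genome_fasta)
    index = load_gtf(cfg.gtf)

    state: dict[str, object] = {}
    manifest_rows = []

    def record(stage: str, inputs: list[str], outputs: list[Path], t0: float):
        manifest_rows.append({
            "stage": stage,
            "inputs": ";".join(str(i) for i in inputs),
            "outputs": ";".join(str(o) for o in outputs),
            "wall_time_s": round(time.monotonic() - t0, 3),
        })

    def require(stage: str, artifact: Path, producer: str):
        if stage in stages:
            return
        if not artifact.exists():
            raise PipelineError(
                f"stage {producer!r} requires output of stage {stage!r}, "
                f"which was neither requested nor found at {artifact}")

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        if stage == "junctions":
            table, junc_list, orphans = jmod.count_junctions(
                sam_paths, index, genome, cfg.min_anchor_overlap)
            state["junctions"] = (table, junc_list)
            jmod.write_junction_table(out / "junctions_counts.tsv", table, junc_list)
            jmod.write_bed(out / "junctions.bed",
                           [(j.chrom, j.start, j.end, j.id, j.strand)
                            for j in junc_list])
            (out / "junctions_orphans.tsv").write_text(
                "junction_id\n" + "".join(f"{o}\n" for o in orphans))
            record(stage, list(sam_paths.values()),
                   [out / "junctions_counts.tsv", out / "junctions.bed",
                    out / "junctions_orphans.tsv"], t0)
        elif stage == "exons":
            table = jmod.count_exons(sam_paths, index)
            state["exons"] = table
            table.to_tsv(out / "exons_counts.tsv")
            record(stage, list(sam_paths.values()), [out / "exons_counts.tsv"], t0)
        elif stage == "anchors":
            require("junctions", out / "junctions_counts.tsv", stage)
            table, junc_list = _get_junctions(state, out)
            regions, gene_map = [], {}
            for j in junc_list:
                a = jmod.anchor_region(j, len(genome.sequences[j.chrom]))
                regions.append((a.id, a.chrom, a.start, a.end))
                if j.id in table.gene_map:
                    gene_map[a.id] = table.gene_map[j.id]
            anchors = jmod.count_regions(sam_paths, regions, gene_map)
            state["anchors"] = anchors
            anchors.to_tsv(out / "anchors_counts.tsv")
            record(stage, [str(out / "junctions_counts.tsv")],
                   [out / "anchors_counts.tsv"], t0)
        elif stage == "diff":
            require("junctions", out / "junctions_counts.tsv", stage)
            require("anchors", out / "anchors_counts.tsv", stage)
            outputs = _run_diff(cfg, state, out)
            record(stage, [str(out / "junctions_counts.tsv")], outputs, t0)
        elif stage == "judge":
            outputs = _run_judge(cfg, out)
            record(stage, _diff_paths(cfg, out, "junctions"), outputs, t0)
        elif stage == "classes":
            outputs = _run_classes(cfg, state, out, genome)
            record(stage, _diff_paths(cfg, out, "junctions"), outputs, t0)
        elif stage == "scanrbp":
            outputs = _run_scanrbp(cfg, out)
            record(stage, [str(cfg.pwm_path)] if cfg.pwm_path else [], outputs, t0)
        elif stage == "report":
            from .report import build_report
            manifest = pd.DataFrame(manifest_rows)
            path = build_report(manifest, out)
            record(stage, [], [path], t0)

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def _get_junctions(state, out: Path):
    if "junctions" in state:
        return state["junctions"]
    table = CountTable.from_junction_tsv(out / "junctions_counts.tsv")
    junc = [jmod.Junction.parse(f) for f in table.feature_ids]
    return table, junc


def _read_junction_table(path: Path) -> CountTable:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in df.columns
                  if c not in ("junction_id", "chrom", "start", "end", "strand",
                               "gene_id")]
    counts = df[sample_ids].to_numpy()
    libs = counts.sum(axis=0).astype(float)
    libs[libs == 0] = 1.0
    gene_map = {f: g for f, g in zip(df["junction_id"], df["gene_id"].fillna(""))
                if isinstance(g, str) and g}
    return CountTable(list(df["junction_id"]), sample_ids, counts, libs,
                      gene_map=gene_map)


# allow reading back the junction writer's format as a CountTable
CountTable.from_junction_tsv = staticmethod(_read_junction_table)


def _diff_paths(cfg: RunConfig, out: Path, feature_type: str) -> list[str]:
    return [str(out / f"diff_{feature_type}_{c.name}.tsv") for c in cfg.comparisons]


def _run_diff(cfg: RunConfig, state, out: Path) -> list[Path]:
    table, junc_list = _get_junctions(state, out)
    anchors = state.get("anchors")
    if anchors is None:
        anchors = CountTable.from_tsv(out / "anchors_counts.tsv")
    exons = state.get("exons")
    gene_table = table.gene_totals()
    outputs = []
    for c in cfg.comparisons:
        todo = [("junctions", table), ("anchors", anchors)]
        if exons is not None:
            todo.append(("exons", exons))
        for feature_type, tab in todo:
            res = diffuse.diff_usage_test(tab, tab.gene_map, c)
            path = out / f"diff_{feature_type}_{c.name}.tsv"
            diffuse.write_results(path, res, c.name, feature_type)
            outputs.append(path)
        gres = diffuse.diff_gene_test(gene_table, c)
        path = out / f"diff_genes_{c.name}.tsv"
        diffuse.write_results(path, gres, c.name, "genes")
        outputs.append(path)
    return outputs


def _run_judge(cfg: RunConfig, out: Path) -> list[Path]:
    outputs = []
    per_comp = {}
    for c in cfg.comparisons:
        jpath = out / f"diff_junctions_{c.name}.tsv"
        gpath = out / f"diff_genes_{c.name}.tsv"
        if not jpath.exists() or not gpath.exists():
            raise PipelineError(f"stage 'judge' requires outputs of stage 'diff' "
                                f"for comparison {c.name!r}")
        jres = pd.read_csv(jpath, sep="\t")
        gres = pd.read_csv(gpath, sep="\t")
        points, _dropped = judge.judge_points(jres, gres)
        if len(points) >= 2:
            summary = judge.judge_score(points)
            path = out / f"judge_{c.name}.tsv"
            judge.write_judge_tsv(path, points, summary)
            judge.plot_judge(out / f"judge_{c.name}.png", points, summary,
                             title=f"juDGE {c.name}")
            outputs += [path, out / f"judge_{c.name}.png"]
        per_comp[c.name] = jres
    if len(cfg.comparisons) >= 2:
        logfc = pd.DataFrame({name: df.set_index("feature_id")["logFC"]
                              for name, df in per_comp.items()}).T
        fdr = pd.DataFrame({name: df.set_index("feature_id")["fdr"]
                            for name, df in per_comp.items()}).T
        try:
            order, _linkage, filtered, newick = judge.cluster_comparisons(
                logfc.fillna(0.0), fdr.fillna(1.0),
                cfg.thresholds.judge_filter_fdr)
            (out / "judge_cluster.txt").write_text(
                "order\t" + "\t".join(order) + "\n" + newick + "\n")
            filtered.to_csv(out / "judge_cluster_matrix.tsv", sep="\t")
            outputs += [out / "judge_cluster.txt", out / "judge_cluster_matrix.tsv"]
        except ValueError as exc:
            logger.warning("judge clustering skipped: %s", exc)
    return outputs


def _run_classes(cfg: RunConfig, state, out: Path, genome: Genome) -> list[Path]:
    table, junc_list = _get_junctions(state, out)
    jmap = {j.id: j for j in junc_list}
    outputs = []
    for c in cfg.comparisons:
        jres = pd.read_csv(out / f"diff_junctions_{c.name}.tsv", sep="\t")
        apath = out / f"diff_anchors_{c.name}.tsv"
        ares = pd.read_csv(apath, sep="\t") if apath.exists() else \
            pd.DataFrame(columns=["feature_id", "logFC"])
        for scheme, sets in (
            ("splice_site", siteclass.classify_splice_sites(
                jres, jmap, genome, cfg.thresholds, cfg.flank)),
            ("donjuan", siteclass.donjuan_classify(
                jres, ares, jmap, genome, cfg.thresholds, cfg.flank)),
        ):
            class_dir = out / f"classes_{scheme}_{c.name}"
            paths = siteclass.emit_class_fasta(sets, class_dir)
            tpath = out / f"classes_{scheme}_{c.name}.tsv"
            siteclass.write_class_table(tpath, sets)
            outputs += [tpath, *paths.values()]
    return outputs


def _run_scanrbp(cfg: RunConfig, out: Path) -> list[Path]:
    if cfg.pwm_path is None:
        logger.info("scanrbp stage skipped: no PWM file configured")
        return []
    pwms = scanrbp.load_pwms(cfg.pwm_path)
    outputs = []
    for c in cfg.comparisons:
        sets = _reload_classes(out, "splice_site", c.name, cfg.flank,
                               cfg.thresholds)
        if sets is None:
            raise PipelineError("stage 'scanrbp' requires outputs of stage "
                                f"'classes' for comparison {c.name!r}")
        nonempty = [n for n, recs in sets.classes.items() if recs]
        profiles = [scanrbp.class_profile(p, sets, name)
                    for p in pwms for name in nonempty]
        rnamap_path = out / f"rnamap_{c.name}.tsv"
        scanrbp.write_rnamap_tsv(rnamap_path, profiles)
        outputs.append(rnamap_path)
        rows = []
        for p in pwms:
            for target in ("enhanced", "repressed"):
                if target in nonempty and "control" in nonempty:
                    t_obs, pval = scanrbp.permutation_pvalue(
                        p, sets, target, "control", n_iter=cfg.scan_n_iter,
                        seed=cfg.seed)
                    rows.append({"motif_id": p.motif_id, "target": target,
                                 "control": "control", "T_obs": t_obs, "p": pval,
                                 "n_iter": cfg.scan_n_iter, "seed": cfg.seed})
        sig_path = out / f"rnamap_significance_{c.name}.tsv"
        scanrbp.write_significance_tsv(sig_path, rows)
        outputs.append(sig_path)
    return outputs


def _reload_classes(out: Path, scheme: str, comp: str, flank: int,
                    thresholds: Thresholds):
    """Rebuild a ClassedSiteSets from emitted per-class FASTA files."""
    class_dir = out / f"classes_{scheme}_{comp}"
    if not class_dir.exists():
        return None
    names = (siteclass.SPLICE_SITE_CLASSES if scheme == "splice_site"
             else siteclass.DONJUAN_CLASSES)
    classes = {}
    for name in names:
        path = class_dir / f"{scheme}_{name}.fa"
        records = []
        if path.exists():
            for header, seq in _iter_fasta(path):
                jid, cls, span = header.split("|")
                chrom, se, strand = span.rsplit(":", 2)
                s, e = se.split("-")
                records.append(siteclass.SiteRecord(
                    jid, chrom, int(s), int(e), strand, seq, 0.0, 1.0))
        classes[name] = records
    return siteclass.ClassedSiteSets(scheme, classes, thresholds, flank)


def _iter_fasta(path: Path):
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)
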