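import numpy as np
import pandas as pd
import pytest

from splicelab.diffuse import Comparison
from splicelab.genome import load_fasta, load_gtf
from splicelab.synthetic import SimConfig, make_toy_genome, simulate_spliced_reads


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Small synthetic dataset: genome, annotation, spliced SAMs, truth."""
    out = tmp_path_factory.mktemp("toy")
    cfg = SimConfig(seed=11, n_genes=10, n_planted=2, depth=80)
    genome_path, gtf_path, truth = make_toy_genome(cfg, out)
    genome = load_fasta(genome_path)
    sheet, tallies = simulate_spliced_reads(
        cfg, genome.sequences[cfg.chrom_name], truth, out)
    return {
        "cfg": cfg, "dir": out, "genome_path": genome_path,
        "gtf_path": gtf_path, "truth": truth, "genome": genome,
        "index": load_gtf(gtf_path), "sheet": sheet, "tallies": tallies,
        "sam_paths": dict(zip(sheet["sample_id"], sheet["path"])),
        "comparison": Comparison(
            "test_vs_control",
            ("test1", "test2", "test3"),
            ("control1", "control2", "control3")),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequences(rng, n, length):
    return ["".join(seq) for seq in rng.choice(list("ACGT"), size=(n, length))]


class SequenceSets:
    """Minimal stand-in for ClassedSiteSets: named sequence lists + flank."""

    def __init__(self, classes: dict[str, list[str]], flank: int | None = None):
        self.classes = classes
        self.flank = flank if flank is not None else (
            (len(next(iter(classes.values()))[0]) - 1) // 2)

    def sequences(self, name):
        return self.classes.get(name, [])


@pytest.fixture()
def make_results():
    """DiffResult-shaped DataFrame factory."""

    def _make(rows):
        return pd.DataFrame(rows, columns=["feature_id", "gene_id", "logFC",
                                           "p", "fdr"])

    return _make
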