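"""Feature x sample count container shared by junctions, exons, anchors and genes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Integer count matrix with per-sample library sizes.

    ``counts`` has one row per feature id and one column per sample id.
    ``library_sizes`` (total primary aligned reads, or simulated
    equivalents) are used for between-sample normalization.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray
    #: optional feature -> gene assignment
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be > 0")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().reset_index()
        df.insert(1, "gene_id", [self.gene_map.get(f, "") for f in self.feature_ids])
        with open(path, "w") as fh:
            fh.write("# library_sizes\t" + "\t".join(
                f"{s}={int(l)}" for s, l in zip(self.sample_ids, self.library_sizes)) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# library_sizes\t"):
                raise ValueError(f"{path}: missing library_sizes header line")
            libs = dict(item.split("=") for item in header.strip().split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        sample_ids = [c for c in df.columns if c not in ("feature_id", "gene_id")]
        gene_map = {}
        if "gene_id" in df.columns:
            gene_map = {
                f: g for f, g in zip(df["feature_id"], df["gene_id"].fillna(""))
                if g
            }
        return cls(
            feature_ids=list(df["feature_id"]),
            sample_ids=sample_ids,
            counts=df[sample_ids].to_numpy(dtype=np.int64),
            library_sizes=np.array([float(libs[s]) for s in sample_ids]),
            gene_map=gene_map,
        )

    def gene_totals(self) -> "CountTable":
        """Aggregate feature counts to per-gene totals (features without a
        gene assignment are dropped)."""
        genes = sorted({g for g in self.gene_map.values()})
        gene_idx = {g: i for i, g in enumerate(genes)}
        totals = np.zeros((len(genes), len(self.sample_ids)), dtype=self.counts.dtype)
        for i, f in enumerate(self.feature_ids):
            g = self.gene_map.get(f)
            if g is not None:
                totals[gene_idx[g]] += self.counts[i]
        return CountTable(genes, list(self.sample_ids), totals,
                          self.library_sizes.copy(),
                          gene_map={g: g for g in genes})
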