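"""PWM scanning of donor-window sequences and class-level RNA-maps.

A position weight matrix (per-position nucleotide probabilities of an
RNA-binding protein's motif) is scored against each window position as
a log2-odds sum over the motif length relative to a background
distribution. Scores are binarized — strictly positive means a hit —
and hits are averaged per position over all sequences of a class,
yielding an RNA-map of predicted binding around the donor site.
Class differences (e.g. repressed vs control) are assessed with a label
permutation test on the position-summed coverage difference.

Windows containing N never count as hits; their score is a -inf
sentinel that binarizes to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: probability floor replacing exact zeros before log-odds
PROB_FLOOR = 1e-6
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
DEFAULT_N_ITER = 100_000


@dataclass
class PWM:
    motif_id: str
    protein: str
    matrix: np.ndarray      # (L, 4) probabilities in A,C,G,T order
    background: np.ndarray  # (4,) probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be (L >= 1, 4)")
        if (self.matrix < 0).any() or (self.background < 0).any():
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2 odds with zero probabilities floored and renormalized."""
        mat = np.maximum(self.matrix, PROB_FLOOR)
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.maximum(self.background, PROB_FLOOR)
        bg = bg / bg.sum()
        return np.log2(mat / bg)


UNIFORM_BACKGROUND = np.full(4, 0.25)


def pwm_from_consensus(motif: str, motif_id: str | None = None,
                       match_prob: float = 0.99) -> PWM:
    """A sharply peaked PWM for a consensus sequence (U treated as T).

    At the default sharpness a window scores positive against a uniform
    background only when nearly all positions match the consensus (one
    mismatch in a 7-mer still hits; two do not), which is the intended
    behavior for consensus-motif detection.
    """
    L = len(motif)
    mat = np.full((L, 4), (1 - match_prob) / 3)
    for i, base in enumerate(motif.upper()):
        mat[i, BASE_INDEX[base]] = match_prob
    return PWM(motif_id or motif, motif_id or motif, mat, UNIFORM_BACKGROUND.copy())


def load_pwms(path: str | Path, dialect: str = "matrix_tsv") -> list[PWM]:
    """Read PWMs from the matrix_tsv dialect.

    Blocks separated by blank lines: a ``motif_id<TAB>protein`` header
    followed by L rows of four tab-separated probabilities in A,C,G,U
    order (U stored as T). Rows off unit sum by more than 1e-3 are
    renormalized with a warning; a negative entry rejects the block.
    An optional ``background<TAB>a,c,g,u`` line after the header
    overrides the uniform background.
    """
    if dialect != "matrix_tsv":
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    pwms: list[PWM] = []
    with open(path) as fh:
        blocks = [b for b in fh.read().split("\n\n") if b.strip()]
    for block in blocks:
        lines = [ln for ln in block.strip().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        motif_id = header[0]
        protein = header[1] if len(header) > 1 else motif_id
        background = UNIFORM_BACKGROUND.copy()
        body = lines[1:]
        if body and body[0].lower().startswith("background\t"):
            background = np.array([float(x) for x in body[0].split("\t")[1].split(",")])
            background = background / background.sum()
            body = body[1:]
        rows = []
        reject = False
        for ln in body:
            vals = np.array([float(x) for x in ln.split("\t")])
            if (vals < 0).any():
                logger.warning("load_pwms: negative entry in block %r, block rejected",
                               motif_id)
                reject = True
                break
            s = vals.sum()
            if abs(s - 1.0) > 1e-3:
                logger.warning("load_pwms: %r row sums to %.4f, renormalized",
                               motif_id, s)
            rows.append(vals / s if s > 0 else np.full(4, 0.25))
        if reject or not rows:
            continue
        pwms.append(PWM(motif_id, protein, np.vstack(rows), background))
    logger.info("load_pwms: %d PWMs loaded from %s", len(pwms), path)
    return pwms


def write_pwms(path: str | Path, pwms: list[PWM]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pwms):
            if i:
                fh.write("\n")
            fh.write(f"{p.motif_id}\t{p.protein}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def encode_sequence(seq: str) -> np.ndarray:
    """Base indices (A=0..T=3); N and other ambiguity codes become -1."""
    idx = np.full(len(seq), -1, dtype=np.int64)
    for base, i in BASE_INDEX.items():
        idx[np.frombuffer(seq.upper().encode(), dtype=np.uint8) ==
            ord(base)] = i
    return idx


def logodds_scan(p: PWM, seq: str) -> np.ndarray:
    """Log2-odds score at every window start of *seq*.

    Vector length is ``len(seq) - L + 1`` (empty when the sequence is
    shorter than the motif). Windows containing any non-ACGT base score
    ``-inf`` and are treated as non-hits downstream.
    """
    L = p.length
    n = len(seq) - L + 1
    if n <= 0:
        return np.array([])
    idx = encode_sequence(seq)
    lo = p.log_odds()
    valid = idx >= 0
    safe_idx = np.where(valid, idx, 0)
    scores = np.zeros(n)
    window_valid = np.ones(n, dtype=bool)
    for k in range(L):
        scores += lo[k, safe_idx[k:k + n]]
        window_valid &= valid[k:k + n]
    scores[~window_valid] = -np.inf
    return scores


def binarize(scores: np.ndarray) -> np.ndarray:
    """Strictly positive scores become 1; zero, negative or -inf become 0."""
    return (np.asarray(scores) > 0).astype(np.int8)


@dataclass
class BindingProfile:
    motif_id: str
    class_name: str
    positions: np.ndarray  # window-start offsets relative to the donor site
    coverage: np.ndarray   # per-position mean of binarized hits, in [0, 1]
    n_sequences: int


def _hit_matrix(p: PWM, sequences: list[str]) -> np.ndarray:
    mats = [binarize(logodds_scan(p, s)) for s in sequences]
    return np.vstack(mats)


def class_profile(p: PWM, sets, class_name: str) -> BindingProfile:
    """RNA-map for one class: per-position hit frequency around the donor site.

    All sequences of a class share one length (donor windows), with the
    donor base at the centre; offsets run from -flank to
    flank - L + 1.
    """
    sequences = sets.sequences(class_name)
    if not sequences:
        raise ValueError(f"class {class_name!r} is empty")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"class {class_name!r} sequences have unequal lengths")
    hits = _hit_matrix(p, sequences)
    flank = getattr(sets, "flank", (lengths.pop() - 1) // 2)
    positions = np.arange(hits.shape[1]) - flank
    return BindingProfile(p.motif_id, class_name, positions,
                          hits.mean(axis=0), len(sequences))


def permutation_pvalue(p: PWM, sets, target_class: str, control_class: str,
                       n_iter: int = DEFAULT_N_ITER, seed: int | None = None,
                       ) -> tuple[float, float]:
    """Permutation significance of the class difference in total coverage.

    The statistic is T = sum over positions of (coverage_target -
    coverage_control). The null pools both classes' sequences and
    re-splits them into the original class sizes *n_iter* times; the
    two-sided p uses the add-one estimator
    ``(1 + #{|T_perm| >= |T_obs|}) / (n_iter + 1)``, so p is never 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seqs_t = sets.sequences(target_class)
    seqs_c = sets.sequences(control_class)
    if not seqs_t or not seqs_c:
        raise ValueError("both classes must be non-empty")
    if len(seqs_t) < 2 or len(seqs_c) < 2:
        logger.warning("permutation_pvalue: class size < 2; p-value is low-powered")
    n_t, n_c = len(seqs_t), len(seqs_c)
    # per-sequence total hit count: the positional sum collapses to a
    # 1-D quantity, so permutations only shuffle scalars
    h = _hit_matrix(p, seqs_t + seqs_c).sum(axis=1).astype(float)
    t_obs = h[:n_t].mean() - h[n_t:].mean()

    # canonical null: sorted pooled values, subsets of the smaller class
    # size (a subset and its complement give the same |T|), so the p
    # estimate is exactly invariant under swapping target and control
    rng = np.random.default_rng(seed)
    n = n_t + n_c
    a, b = min(n_t, n_c), max(n_t, n_c)
    h_sorted = np.sort(h)
    total = h.sum()
    count = 0
    chunk = max(1, min(n_iter, int(2e7 // max(n, 1))))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        subset = rng.random((m, n)).argsort(axis=1)[:, :a]
        sum_a = np.take(h_sorted, subset).sum(axis=1)
        t_perm = sum_a / a - (total - sum_a) / b
        count += int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
        done += m
    pval = (1 + count) / (n_iter + 1)
    return float(t_obs), float(pval)


def write_rnamap_tsv(path: str | Path, profiles: list[BindingProfile]) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tclass\toffset\tcoverage\n")
        for pr in profiles:
            for pos, cov in zip(pr.positions, pr.coverage):
                fh.write(f"{pr.motif_id}\t{pr.class_name}\t{int(pos)}\t{cov:.6g}\n")


def write_significance_tsv(path: str | Path, rows: list[dict]) -> None:
    import pandas as pd
    pd.DataFrame(rows, columns=["motif_id", "target", "control", "T_obs", "p",
                                "n_iter", "seed"]).to_csv(path, sep="\t", index=False)


def plot_rnamap(path: str | Path, profiles: list[BindingProfile],
                title: str = "RNA-map") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for pr in profiles:
        ax.plot(pr.positions, pr.coverage, label=f"{pr.class_name} (n={pr.n_sequences})")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("offset from donor site (nt)")
    ax.set_ylabel("binding frequency")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
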