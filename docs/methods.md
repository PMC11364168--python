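# Methods

This note documents the models, conventions and numerical choices
behind `splicelab`, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and junction conventions

All internal coordinates are 0-based half-open; the GTF reader converts
from 1-based inclusive on load and the browser-URL writer converts back
on output — nowhere else. A junction is the intron interval
`[start, end)`; its id `chrom:start-end:strand` round-trips through
parsing. The **donor site coordinate is the first intronic base**
(`start` on `+`, `end − 1` on `−`). This is a convention, not a fact of
nature: the alternative (last exonic base) shifts every window by one
base. The donor window for flank *f* has length 2f + 1 (161 nt at the
default f = 80) with the donor base at the centre, so that the window
is symmetric around a single centre position; the window is emitted in
transcript orientation (reverse-complemented for `−` junctions). The
anchor is the 15-nt exonic interval immediately 5′ of the donor site
(`[start−15, start)` on `+`, `[end, end+15)` on `−`); windows or
anchors running off a chromosome end are flagged clipped and excluded
from class sequence sets rather than padded.

A read supports a junction only with ≥ 8 aligned (M/=/X) bases on each
side of the N gap (`min_anchor_overlap`, exposed); this is the usual
guard against spurious single-anchor junctions. Junction strand comes
from the unique gene containing both intron ends; failing that, from
the intron's terminal dinucleotides (GT..AG forward / CT..AC reverse);
failing both, `+` with an *unoriented* flag. Junctions whose ends fall
in zero or several genes go to an orphan list and are never assigned
to a gene, because the usage test requires unambiguous within-gene
grouping. Library size is the count of primary aligned reads (flags
0x4/0x100/0x800 skipped) — the simplest reproducible normalizer.

## Differential usage and expression

The usage test treats each feature–sample observation as a pair
(feature count k, gene total n) and scores equal proportions across
conditions. Overdispersion enters as a beta-binomial intra-class
correlation ρ estimated per gene by method of moments: standardized
squared residuals around the condition-pooled proportion have
expectation 1 + (n̄ − 1)ρ, so ρ is read off the chi-square/df ratio and
floored at 0. The score statistic uses pooled-proportion variance with
the (1 + (n − 1)ρ) inflation; at ρ = 0 it is algebraically the pooled
2×2 chi-square, which the tests verify to 1e-6 against
`scipy.stats.chi2_contingency`. Two-sided p from the normal
approximation; this is adequate at the depths the tool targets
(tens to hundreds of reads per gene) and the type-I calibration test
(null generator, 2000 features) holds it to 0.05 ± 0.02. The reported
logFC is the feature's normalized logFC minus its gene's — the usage
effect — with a pseudo-count prior of 0.125 per observation keeping it
finite at zero counts. Single-feature genes are excluded (usage is
identically 1); genes with an all-zero side are reported untestable
with p = 1 rather than dropped.

Gene-level expression uses a Wald test on log(rate_t) − log(rate_c)
with plug-in negative-binomial variance (moment dispersion from
within-condition normalized counts, floored at 0; Poisson Wald at 0).
BH adjustment is applied separately per comparison and feature type
(junctions, exons, anchors, genes), since the result tables are
consumed separately downstream. These are deliberate clean-room
implementations of the two-group contracts; quasi-likelihood F-tests,
TMM normalization and empirical-Bayes shrinkage are out of scope, and
numerical agreement with R implementations of similar contracts is not
claimed.

## juDGE

Points pair junction logFC (y) with the junction's gene logFC (x);
the score is the **population** (divide-by-n) standard deviation ratio
stdev(x)/stdev(y), which keeps the two-point identities exact and is
immaterial at realistic n. All junctions with a tested gene enter by
default (an FDR filter is available but off). stdev(y) = 0 yields an
explicitly undefined score, not infinity. Comparison clustering filters
to features with FDR < 0.05 in ≥ 1 comparison, then applies average
linkage on correlation distance (1 − Pearson r); comparisons are sorted
by name before linkage so merge ties break lexicographically; constant
logFC vectors get distance 1 (treated as uncorrelated) instead of NaN.

## Donor-site classification

`splice_site` scheme: enhanced = FDR < 0.05 and logFC > 0.5;
repressed = FDR < 0.05 and logFC < −0.5; control = FDR > 0.5, with no
effect-size restriction on controls (a deliberate literal reading —
controls are "clearly unregulated", not "unchanged"). The repressed
cut-off is symmetric to the enhanced one by default; the asymmetric
variant −0.05 sometimes quoted for this rule is available by passing
`Thresholds(site_rep_lfc=-0.05)`. Junctions that are significant but
small-effect, or with FDR between 0.05 and 0.5, are recorded as
unassigned, never silently dropped.

DonJuAn: candidates are junctions with FDR < 0.05; the decision signal
combines junction and anchor logFC, by arithmetic mean by default.
"Combine" is genuinely underdetermined, so the strategy is a parameter:
`mean` (default), `min` (the signal of smaller magnitude — the
conservative reading), or `anchor_only` (anchors as the sole effect
measure, motivated by junction reads being scarce). A junction without
an anchor result falls back to its own logFC with a logged count.
Included = combined > 1, skipped = combined < −1, control = FDR > 0.5.

## PWM scanning and permutation significance

PWMs are per-position probabilities over A,C,G,T (U mapped to T) with a
background (uniform unless the file overrides it). Exact zeros are
floored at 1e-6 and rows renormalized before log2-odds, so legitimate
PWM zeros cannot produce −inf for an otherwise-matching window; windows
containing N score a −inf sentinel and can never be hits. Binarization
is strictly `score > 0` — a window exactly at background (score 0)
is not a hit, which makes the degenerate uniform-PWM case score all
zeros. RNA-maps average binarized hits per window-start offset
(position 0 = donor site); a raw-signal mode is not provided because
the hit-frequency map is the quantity the class comparison uses.

Significance of a class difference uses label permutation: the
statistic T is the position-summed coverage difference, which collapses
to a difference of per-sequence mean hit counts, so each permutation
only reshuffles scalars. The null re-splits the pooled sequences into
the original class sizes; the implementation draws subsets of the
smaller class size from the sorted pooled values, making the Monte
Carlo estimate exactly invariant under swapping target and control.
The two-sided p uses the add-one estimator (1 + #{|T⋆| ≥ |T|})/(B + 1),
bounded below by 1/(B + 1). The default B = 100 000; tests and the
desk-scale experiments use 500–2000. Because T is a mean of integer
hit counts, sharply peaked PWMs on short sequences produce heavily tied
null distributions and hence *super-uniform* (conservative) p-values;
the calibration experiment therefore probes uniformity with a
moderately informative 5-mer (match probability 0.8) on 161-nt
sequences (~16 hits/sequence), where the statistic is near-continuous.
`pwm_from_consensus` defaults to match probability 0.99, at which a
7-mer window still scores positive with one mismatch but not two —
the intended semantics for consensus-motif detection.

## Synthetic data: what it emulates, what it does not

The generator is a pure function of `SimConfig` (same seed ⇒
byte-identical FASTA/GTF/SAM/TSV; all files are really written and
re-read so the parsers are exercised). Genes alternate strands along
one chromosome; every intron carries GT..AG on its transcribed strand
so strand inference is testable; exon/intron lengths are uniform in
(80–160)/(200–400) nt. Reads are single-end, error-free, constant
quality, with fM–N–fM CIGARs (f = 30) centred on a junction; per-gene
totals are negative-binomial (gamma–Poisson, default dispersion 0.05 —
a typical technical-replicate scale) and junction counts multinomial
within the gene. A planted gene shifts its first junction's usage
proportion from 1/J to 1/J + Δ (0.5 → 0.9 at the default Δ = 0.4,
J = 2) in the test condition; its gene-mates shift complementarily and
are tracked as "siblings", distinct from nulls, so false-discovery
accounting does not mislabel genuinely shifted features. Motif
planting inserts the configured 7-mer (default AGAGTAA, a known
splicing-modifier-associated donor motif) at 60%/5% target/background
rates at positions overlapping ±10 nt of the donor site.

What passing these tests shows: the statistics are correctly
implemented and calibrated under their own model, and the full chain
(SAM → counts → test → classes → scan) is internally consistent. What
they do not show: robustness to alignment artifacts, multi-mapping,
PCR duplication, paired-end dependence, annotation errors, or
non-canonical splice sites — real-data features the generator
deliberately omits.

## Problem sizes and defaults

The headline recovery experiment uses 1000 two-junction genes
(2000 features), 20 planted shifts of Δ = 0.4, expected depth 200
reads/junction/sample, 3 vs 3 — roughly the informative-read scale of a
small perturbation study and large enough for stable sensitivity and
false-discovery estimates. Calibration experiments use ≥ 2000 features
(type-I) and 200 permutation repeats at B = 500. `scripts/acceptance.py`
re-runs all of these from one command-line seed.

## Known limitations

Only two-group comparisons; no multi-factor designs. Acceptor-site
classification is not implemented (the donor-site rules have printed
thresholds; acceptor rules would be guesses). The usage test's normal
approximation degrades below ~10 reads per gene total; such genes pass
through with conservative p rather than being filtered. The interval
index assumes annotations fit in memory; no on-disk index is built.
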