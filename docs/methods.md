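# Methods

This note records the models, conventions and numerical choices behind
`mirkd`, in the order the pipeline runs.

## Synthetic study generator

**What it emulates.** A paired-design whole-blood small-RNA study: each of
`n_pairs` subjects contributes one acute and one convalescent library
(an unpaired mode generates an acute-vs-control contrast instead). True
per-(miR, library) counts follow a negative binomial with mean
`s_j · q_i(condition)` and variance `mean + α·mean²`, where `s_j` is a
per-library depth factor drawn log-normally around 1 (σ = 0.15), `q_i` is
a log-normal baseline abundance (σ = 1.2, star arms scaled to 12% of
mature), and acute means equal convalescent means times
`2^planted_log2fc`. `α = 0` degenerates to Poisson. A fold change planted
under a locus id applies to both arms of that locus (duplex arms are
co-transcribed); a row-level key with a `*` suffix can set a star arm
separately.

**Reference.** A 50 kb mini genome on 2 chromosomes carries each precursor
(reverse-complemented on the minus strand) and each ncRNA verbatim at
non-overlapping positions with random flanking DNA. Precursors are
8 nt flank + mature + 15 nt loop + star-sized segment + 8 nt flank; mature
lengths are 21/22/23 nt with probabilities 0.25/0.50/0.25, giving the
expected 22-nt modal insert length. Star arms are annotated for a
configurable fraction of loci (default 0.4) and are independent random
sequences — hairpin self-complementarity is deliberately not modeled, both
because secondary structure is out of scope and because a
reverse-complement star would make reads ambiguous between strands. After
assembly the builder verifies every annotated arm occurs exactly once in
the genome (both strands) and retries with a fresh internal stream
otherwise; collisions have probability ~4^-21 per arm, so this is
insurance, not a code path that triggers in practice.

**Reads.** Each counted read is its arm sequence shifted by an isomiR
offset pair drawn from `isomir_offset_probs` (defaults: 5' offsets
−1/0/+1 at 0.05/0.90/0.05, 3' offsets −2…+2 at 0.06/0.14/0.60/0.14/0.06,
independent — 3' variation dominates 5' variation 4:1, matching the
3'-terminal heterogeneity of real small-RNA libraries), with the 21-nt
adapter appended, random padding, and truncation to the 36-nt instrument
read length. Noise channels, as fractions of library size: ncRNA fragments
0.10, unmappable junk 0.03, out-of-window inserts 0.04 (split evenly
between < 17 nt and 28–30 nt), adapter-free reads 0.05 (the reported
no-adapter rate of such libraries is ~5–6%). Qualities are per-base
discretized normal (mean 35, sd 4, clamped to [2, 40]); 2% of reads get
one sub-Q10 base inside the insert to exercise the quality filter.

Two determinism guarantees matter downstream. First, the whole generator
is a pure function of the configuration: identical configs give
byte-identical FASTA/GFF3/FASTQ/TSV output. Second, per-read truth labels
are *guaranteed*, not merely probable: the adapter is a fixed random 21-mer
screened so that every self-overlap of length ≥ 5 carries ≥ 3 mismatches
(so the adapter can never align across the insert/adapter junction within
the 2-mismatch budget), and no-adapter, junk, long-insert and
ncRNA-fragment reads are rejection-sampled through the package's own
trimmer (junk also through the genome index). Each sidecar records the
read's true class and its expected filter fate under the documented
precedence, making exact FilterStats and count-matrix comparisons possible.

**What it does not emulate** (hence what passing tests do not show about
real data): sequencing errors inside the insert (qualities vary, base
calls do not), mismatch-tolerant mapping ambiguity on a real genome's
repeat structure, RNA-ligase sequence bias, multi-locus miR families with
identical mature sequences, and realistic library sizes (defaults are
2000 reads/library and 50 loci — chosen so a full 24-library study runs in
seconds while leaving every per-locus count large enough to test against).

## Preprocessing

The only mismatch-tolerant alignment in the pipeline is the adapter
search: the leftmost position where the adapter prefix matches the read
suffix with ≤ 2 mismatches; a terminal partial overlap of length
`o ≥ 6` gets the pro-rated budget `floor(2·o/21)`. The mismatch budget is
read as an adapter-alignment property because all reference mapping is
explicitly exact. Length bounds are inclusive ([17, 27]); the quality rule
defaults to minimum per-base Phred ≥ 10 over the trimmed insert (the
strictest defensible reading), with a mean-quality mode available.
Categories are assigned with fixed precedence
no-adapter → too-short → too-long → low-quality so each read is counted
exactly once and the category tallies always sum to the total. A trimmed,
qualified insert contains no further adapter match, so re-trimming finds
nothing to remove (the idempotence property as it applies to a trimmer
that flags adapter-free input).

## Annotation

Exact matching uses a 12-mer dictionary with full verification, queried on
both strands; it is tested equivalent to a naive scan. Decision order per
collapsed read: unmapped → ncRNA → known miR → precursor-other → novel
candidate. A known-miR call requires the read inside the precursor on the
annotated strand, the arm's seed (positions 2–8) fully contained in the
read, and both end offsets within 3 nt — the offset cap bounds isomiR
calls at the scale of the read-length window. The default seed is the
standard 5' seed; a 3'-anchored mode (last 7 nt of the arm) is provided
because literature descriptions of seed matching are sometimes anchored at
the 3' end, without taking a position on intent. Reads matching two loci
resolve to the smaller `|offset5| + |offset3|`; exact ties get the
explicit category `multi_mapper` and are excluded from counts. Reads
matching a precursor but no arm are reported as `precursor_other` and
excluded from the count matrix. Mature and star arms are separate count
rows. Novel candidates are exported as FASTA with genomic loci for
external hairpin modeling; the hairpin model itself is out of scope.

## Differential expression

The two conditions are compared *unpaired*, matching the classic
count-model workflow even though the design is paired — pairing is used
by the clinical Wilcoxon analyses instead. Size factors are
median-of-ratios over all-positive rows (a pseudo-reference fallback over
positive entries is available for sparse matrices). Dispersion per row is
method of moments on normalized counts,
`α̂ = max(0, (v − q̄·mean(1/s))/q̄²)`, with a least-squares trend
`α_fit(q) = a0/q + a1` fitted over rows with positive `α̂` and the
conservative final rule `α = max(α̂, α_fit(q̄))`. The exact test
conditions on the row total K and sums the probabilities of all splits no
more likely than the observed one (two-sided by summation, not tail
doubling); probabilities use NB laws parametrized by condition-summed
means `q₀·Σs_j` and variances `q₀Σs_j + α·q₀²·Σs_j²`, with the Poisson
limit when the variance does not exceed the mean. Zero-total rows are
dropped before testing and excluded from the BH family (an "expressed"
miR needs at least one read somewhere). BH adjustment delegates to
statsmodels.

Fold change is the ratio of mean normalized counts; the moderated
alternative is the difference of means of the VST
`u(k) = 2·log2(√(αk) + √(αk+1))`, the antiderivative of
`1/√(k + αk²)` scaled so differences approach plain log2 ratios once
`αk ≫ 1` (verified within 1% at α = 0.1, k ≥ 1000). At α = 0 the
transform has no log2 limit, so α is floored at 1e-8 inside the VST; for
near-Poisson rows `vst_log2fc` is therefore strongly shrunk toward 0,
which is the intended moderation behavior at low dispersion.

One property worth stating precisely: multiplying one library's counts by
a constant is *exactly* absorbed at the normalization level (its size
factor grows by exactly that constant relative to the others; all fold
changes are unchanged), but the conditional exact test is **not**
invariant under it — the test conditions on the raw split of the row
total, which the rescaling changes, and a c-scaled count variable is not
NB at c-times the mean. The invariance test asserts the
normalization-level statement.

## Pathway enrichment

The target set is the union over the queried miRs of genes with
miTG score ≥ 0.7 (inclusive; the scores are opaque inputs — their MRE and
conservation components are not re-derived). The universe is all genes in
the pathway database, targets outside it are dropped before testing, and
pathways with < 10 genes are filtered out. The p-value is the upper
hypergeometric tail `P(X ≥ overlap)`, computed with exact integer/rational
arithmetic for universes up to 2000 genes and scipy's survival function
beyond. Raw p-values are reported (no correction), with BH as an option.

## Clinical statistics

qRT-PCR relative abundance is `2^−(Ct_target − Ct_RNU48)` — doubling
efficiency per cycle, normalized to the RNU48 small nucleolar reference;
records missing the reference Ct are skipped with a warning.

Both rank tests are exact by dynamic programming over doubled (hence
integer) average ranks, which handles ties without enumeration blow-up:
the signed-rank null is the convolution of `(1 + x^{2r})/2` over ranks of
the non-zero differences (zeros dropped, exact up to 25 informative
pairs), the Mann–Whitney null is the distribution of the group-A rank sum
over all `C(n, n_A)` assignments (exact up to 25 total). Two-sided
p-values double the smaller tail, capped at 1; beyond the exact limits a
tie-corrected normal approximation with continuity correction takes over.
Both are tested against full enumeration.

Power of the paired design: each replicate draws `n_pairs` differences
from Normal(effect, 1) — "effect size 1" is read as a standardized paired
mean of one SD, the conventional input to this calculation — and applies
the exact two-sided signed-rank test at α. Continuous draws make ties and
zeros probability-zero events, so the untied null distribution is
precomputed once and p-values are looked up, letting 50,000 replicates
run in about a second. At n = 12, effect 1, α = 0.05 the estimate is
≈ 0.85 (Monte-Carlo SE 0.002), consistent with the 86% design power such
studies quote; the null-effect case calibrates to the achievable size of
the discrete test (slightly below the nominal 0.05).

Spearman correlation delegates to scipy (average ranks, then Pearson on
ranks; constant input reported missing). Permutation p-values use a
seeded Monte-Carlo permutation scheme (default 10,000 draws): full
enumeration of n! orderings is infeasible beyond n ≈ 10, so a
Monte-Carlo p with an add-one correction is the declared convention.

Vesicle RNase protection: `1 − level(Triton+RNase)/level(RNase)` — RNase
alone spares membrane-protected RNA, detergent plus RNase does not, so
the drop measures the vesicle-protected share. Values outside [0, 1]
(assay noise) are clamped for reporting with the raw value retained on
the result and logged.

## Problem sizes and runtime

Defaults chosen for desk-scale work: 12 pairs × 2000 reads/library × 50
loci for end-to-end runs (seconds); DE operating characteristics are
assessed on 500-row, 24-library NB matrices (200 null replicates, 5
planted-signal replicates); power uses 50,000 replicates. The full test
suite runs in about a minute on one CPU.

## Known limitations

- Exact substring matching stands in for mismatch-free alignment; there is
  no mismatch-tolerant mapping, so sequencing errors inside an insert make
  it unmappable rather than mis-mapped.
- The conditional exact test enumerates K+1 splits per row; it is meant
  for desk-scale totals (up to ~10⁵ per row), not deeply sequenced data.
- The dispersion trend is fitted by unweighted least squares on the raw
  moment estimates; with very few rows (< 2 positive estimates) the trend
  degenerates to zero and only the per-row estimates floor the final
  values.
- Multi-mapper handling (smallest-total-offset, ties excluded) is a fixed
  convention; real pipelines differ and no option is provided.
- The qRT-PCR model assumes perfect doubling; no efficiency calibration.
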