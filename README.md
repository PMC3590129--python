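# mirkd

Desk-scale re-implementation of a whole-blood small-RNA (miR-ome) analysis
pipeline of the kind used to profile microRNA expression in Kawasaki
disease: paired acute/convalescent small-RNA-seq libraries are trimmed,
filtered, annotated against a miR reference with zero mismatches, tested
for differential expression under a negative-binomial count model, and
followed up with predicted-target pathway enrichment and the clinical
validation statistics (qRT-PCR normalization, exact rank tests, design
power, vesicle RNase protection).

Because raw patient sequencing data of this kind are rarely redistributable,
the package ships a first-class **synthetic-data generator** that emulates
the study design — paired libraries with negative-binomial counts and
planted fold changes, 22-nt-modal mature sequences with 5'/3' isomiR
variation, a ligated 3' adapter, ncRNA contamination and unmappable reads —
with per-read ground-truth sidecars, so every stage of the pipeline is
testable end to end.

## Who this is for

Bioinformaticians who want a small, fully transparent, fully tested model
of the classic small-RNA-seq analysis stack: every statistical primitive
(conditional NB exact test, median-of-ratios normalization,
method-of-moments dispersion with a trend floor, exact tie-adjusted
Wilcoxon/Mann–Whitney, upper-tail hypergeometric Fisher test) is
implemented explicitly and checked against independent oracles.

## The analysis in brief

- **Preprocessing.** The 3' adapter is located by the leftmost alignment of
  its prefix to the read suffix with at most 2 mismatches (pro-rated for
  terminal partial overlaps ≥ 6 nt). Trimmed inserts are kept when
  17 ≤ length ≤ 27 nt with every base at Phred ≥ 10, then collapsed to
  unique sequences with counts.
- **Annotation.** Collapsed reads are classified hierarchically with exact
  (zero-mismatch) matching on both genome strands: unmapped → ncRNA →
  known miR (read inside an annotated precursor on its strand, seed
  positions 2–8 of the mature/star arm contained in the read, end offsets
  ≤ 3 nt) → precursor-other → novel candidate. Mature and star arms are
  counted as separate rows (miR-x vs miR-x\*); isomiR tables record per-arm
  sequence variants, their 5'/3' offsets and the dominant read.
- **Differential expression.** For a count matrix *k_ij* the model is
  NB with variance *μ + α·μ²*: size factors
  *s_j = median_i k_ij / (∏_v k_iv)^{1/m}*, per-row method-of-moments
  dispersion floored by an *a₀/q + a₁* trend, and a conditional exact test
  that enumerates every split (a, K−a) of a row's total K between
  conditions. BH adjustment across non-zero rows; fold changes on the
  normalized-mean scale and on a variance-stabilized log2 scale
  *u(k) = 2·log2(√(αk) + √(αk+1))*.
- **Enrichment.** The union of predicted targets of a miR list at
  miTG score ≥ 0.7 is tested per pathway (≥ 10 genes) with the one-sided
  Fisher's exact test, p = P(X ≥ overlap) hypergeometric.
- **Clinical statistics.** qRT-PCR levels as 2^−(Ct − Ct_RNU48); exact
  two-sided Wilcoxon signed-rank and Mann–Whitney tests; Spearman
  correlation; Monte-Carlo power of the 12-pair Wilcoxon design at
  standardized effect 1; and the vesicle protection fraction
  1 − level(Triton+RNase)/level(RNase).

## Worked example

```python
from mirkd import SimulationConfig, run_study, power_paired_wilcoxon

cfg = SimulationConfig(seed=42, n_pairs=12, n_loci=50, library_size=2000,
                       planted_log2fc={"syn-mir-003": 2.0, "syn-mir-011": 1.5})
out = run_study(cfg, "study_out")
print(out["filter_stats"]["acute_01"].as_dict())
print(out["results"].summary(top=3))
res = power_paired_wilcoxon(n_pairs=12, effect_size=1.0, alpha=0.05,
                            reps=50_000, seed=0)
print(f"power = {res.power:.3f} +/- {res.se:.3f}")
```

prints

```
{'total': 2058, 'no_adapter': 109, 'too_short': 41, 'too_long': 38, 'low_quality': 37, 'qualified': 1833}
Negative-binomial differential expression
  contrast:        acute vs convalescent
  miRs tested:     71 (0 all-zero rows dropped)
  significant at BH<0.05: 3

              base_mean  mean_acute  mean_convalescent  fold_change  vst_log2fc  dispersion      pval     padj
mir_id
syn-mir-003       6.038       10.14              1.939        5.229        2.46      0.6603 5.879e-05 0.004174
syn-mir-011       14.41       21.86              6.956        3.143       1.496      0.4286 0.0001698 0.006027
syn-mir-003*      2.679       4.299              1.058        4.062       1.245      0.5851 0.0007986   0.0189
power = 0.850 +/- 0.002
```

Reading this: of the 2058 reads in the first acute library, 1833 survive
the adapter/length/quality filters; the two planted miRs (and the star arm
of the first, which shares its locus-level fold change) are the three
BH-significant rows, recovered with fold changes near their planted values
and in the right direction; and the 12-pair Wilcoxon design has ≈85% power
at a standardized effect of 1.

The same stages are available as a CLI:

```bash
mirkd simulate --seed 42 --n-pairs 12 --out-dir study_out
mirkd preprocess study_out/reads/acute_01.fastq --out-prefix acute_01
mirkd diffexp --counts study_out/count_matrix.tsv \
      --samples study_out/truth/samples.tsv --out de.tsv
mirkd power --n 12 --effect 1 --alpha 0.05 --reps 50000 --seed 0
```

## Layout

```
src/mirkd/
  simulate.py     synthetic reference + truth counts + FASTQ generator
  preprocess.py   adapter trimming, length/quality filters, collapsing
  annotate.py     exact index, hierarchical classifier, isomiRs, count matrix
  diffexp.py      NegativeBinomialDE model -> DEResults (summary, MA plot)
  enrichment.py   miTG-thresholded Fisher pathway enrichment
  clinstats.py    qRT-PCR, exact rank tests, power, vesicle protection
  pipeline.py     end-to-end glue
  cli.py          `mirkd` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
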