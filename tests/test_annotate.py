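"""Exact index, hierarchical classification, isomiR summaries, count matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirkd._seq import revcomp
from mirkd.annotate import (
    Annotator, ExactIndex, build_count_matrix, classify_read,
    summarize_isomirs,
)
from mirkd.preprocess import CollapsedRead


class NaiveIndex:
    """Brute-force substring scan with the ExactIndex query contract."""

    def __init__(self, sequences):
        self.sequences = dict(sequences)

    def query(self, q, both_strands=True):
        if not q:
            return []
        out = []
        queries = [(q, "+")] + ([(revcomp(q), "-")] if both_strands else [])
        for probe, strand in queries:
            for sid, seq in self.sequences.items():
                start = seq.find(probe)
                while start != -1:
                    out.append((sid, start, strand))
                    start = seq.find(probe, start + 1)
        return sorted(set(out))


class TestExactIndex:
    def test_annotated_arm_maps_to_recorded_locus(self, reference):
        index = ExactIndex(reference.genome)
        for loc in reference.loci[:5]:
            g0, g1 = loc.genomic_interval(*loc.arm_interval("mature"))
            hits = index.query(loc.mature_seq)
            assert (loc.chrom, g0, loc.strand) in hits

    def test_n_containing_query_has_no_hits(self, reference):
        index = ExactIndex(reference.genome)
        assert index.query("ACGTNACGTNACGTNAC") == []

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            ExactIndex({})

    def test_agrees_with_naive_scan(self, reference):
        index = ExactIndex(reference.genome)
        naive = NaiveIndex(reference.genome)
        rng = np.random.default_rng(7)
        chroms = list(reference.genome)
        for _ in range(200):
            chrom = chroms[rng.integers(0, len(chroms))]
            L = int(rng.integers(17, 28))
            i = int(rng.integers(0, len(reference.genome[chrom]) - L))
            q = reference.genome[chrom][i:i + L]
            if rng.random() < 0.5:
                q = revcomp(q)
            assert index.query(q) == naive.query(q)


@pytest.fixture(scope="module")
def annotator(reference):
    return Annotator(reference)


def _classify(annotator, seq, count=1):
    return annotator.classify(CollapsedRead(seq, count))


class TestClassifyRead:
    def test_canonical_mature_read(self, reference, annotator):
        loc = reference.loci[0]
        a = _classify(annotator, loc.mature_seq)
        assert (a.category, a.locus_id, a.arm) == ("known_mir",
                                                   loc.locus_id, "mature")
        assert (a.offset5, a.offset3) == (0, 0)

    def test_three_prime_shortened_isomir(self, reference, annotator):
        """A mature read one base shorter at its 3' end is still the same
        miR, recorded with offset3 = -1 (the dominant-read situation)."""
        loc = reference.loci[0]
        a = _classify(annotator, loc.mature_seq[:-1])
        assert a.category == "known_mir" and a.locus_id == loc.locus_id
        assert (a.offset5, a.offset3) == (0, -1)

    def test_five_prime_extended_isomir(self, reference, annotator):
        loc = reference.loci[0]
        extended = loc.precursor_seq[loc.mature_start - 1:loc.mature_end]
        a = _classify(annotator, extended)
        assert a.category == "known_mir"
        assert (a.offset5, a.offset3) == (-1, 0)

    def test_ncrna_fragment_in_genome_is_excluded_from_mirs(
            self, reference, annotator):
        """ncRNA fragments also map to the genome but must be classified as
        ncRNA, never counted as miR."""
        trna = next(r for r in reference.ncrnas if r.rna_class == "tRNA")
        frag = trna.seq[5:27]
        a = _classify(annotator, frag)
        assert a.category == "ncrna" and a.locus_id is None

    def test_unmappable_read(self, annotator):
        rng = np.random.default_rng(0)
        while True:
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 22)])
            if not annotator.genome_index.query(seq):
                break
        assert _classify(annotator, seq).category == "unmapped"

    def test_precursor_internal_read_is_precursor_other(
            self, reference, annotator):
        loc = next(l for l in reference.loci if l.star_start is None)
        # read spanning the loop region downstream of the mature arm
        frag = loc.precursor_seq[loc.mature_end + 4:loc.mature_end + 24]
        a = _classify(annotator, frag)
        assert a.category == "precursor_other"

    def test_offset_beyond_limit_is_precursor_other(self, reference, annotator):
        loc = reference.loci[0]
        a0, a1 = loc.mature_start, loc.mature_end
        frag = loc.precursor_seq[a0 - 4:a1 - 4]   # 5' offset -4
        a = _classify(annotator, frag)
        assert a.category == "precursor_other"

    def test_intergenic_read_is_novel_candidate(self, reference, annotator):
        occupied = []
        for loc in reference.loci:
            occupied.append((loc.chrom, loc.start, loc.end))
        for nc in reference.ncrnas:
            occupied.append((nc.chrom, nc.start, nc.end))
        chrom = list(reference.genome)[0]
        pos = 0
        while any(c == chrom and s - 30 <= pos <= e for c, s, e in occupied):
            pos += 200
        frag = reference.genome[chrom][pos:pos + 22]
        a = _classify(annotator, frag)
        assert a.category == "novel_candidate"

    def test_minus_strand_mature_classified_with_offsets(
            self, reference, annotator):
        loc = next(l for l in reference.loci if l.strand == "-")
        a = _classify(annotator, loc.mature_seq[:-2])
        assert a.category == "known_mir" and a.locus_id == loc.locus_id
        assert (a.offset5, a.offset3) == (0, -2)

    def test_full_library_matches_naive_oracle(self, reference, noisy_study):
        """On a <=50 kb reference, classification via the k-mer index agrees
        with a naive all-substring-scan classifier on every collapsed read."""
        naive_genome = NaiveIndex(reference.genome)
        naive_nc = NaiveIndex({r.id: r.seq for r in reference.ncrnas})
        annot = Annotator(noisy_study["reference"])
        lib = next(iter(noisy_study["assignments"]))
        ref = noisy_study["reference"]
        fast = noisy_study["assignments"][lib]
        for a in fast:
            naive = classify_read(
                CollapsedRead(a.seq, a.count),
                NaiveIndex(ref.genome), ref.loci,
                NaiveIndex({r.id: r.seq for r in ref.ncrnas}))
            assert (naive.category, naive.locus_id, naive.arm,
                    naive.offset5, naive.offset3) == \
                   (a.category, a.locus_id, a.arm, a.offset5, a.offset3)

    def test_order_invariance(self, reference, annotator):
        reads = [CollapsedRead(loc.mature_seq, 1) for loc in reference.loci[:6]]
        fwd = [annotator.classify(r) for r in reads]
        rev = [annotator.classify(r) for r in reversed(reads)]
        assert sorted(a.locus_id for a in fwd) == \
               sorted(a.locus_id for a in rev)


class TestClassificationAgainstTruth:
    def test_zero_noise_categories_match_sidecar(self, noiseless_study):
        """Exhaustive comparison: with no noise every qualified read is a
        known miR at its true locus."""
        truth = noiseless_study["truth"]
        for lib, assigns in noiseless_study["assignments"].items():
            side = pd.read_csv(
                noiseless_study["out_dir"] / "reads" / f"{lib}.truth.tsv",
                sep="\t")
            expected = (side[side["fate"] == "qualified"]
                        .groupby("mir_id").size())
            got: dict[str, int] = {}
            for a in assigns:
                assert a.category == "known_mir"
                key = a.locus_id if a.arm == "mature" else a.locus_id + "*"
                got[key] = got.get(key, 0) + a.count
            assert got == expected.to_dict()

    def test_noisy_study_high_assignment_accuracy(self, noisy_study):
        """With default noise, nearly all miR-derived qualified reads are
        assigned to their true locus."""
        counts = noisy_study["counts"]
        correct = 0
        total = 0
        for lib in counts.columns:
            side = pd.read_csv(
                noisy_study["out_dir"] / "reads" / f"{lib}.truth.tsv", sep="\t")
            expect = (side[(side["category"] == "mir")
                           & (side["fate"] == "qualified")]
                      .groupby("mir_id").size())
            total += int(expect.sum())
            for rid, n in expect.items():
                correct += min(int(counts.loc[rid, lib]), int(n))
        assert total > 0 and correct / total >= 0.99


class TestIsomirSummary:
    def _assignments(self, mix):
        out = {}
        for sample, items in mix.items():
            out[sample] = [
                a for a in items
            ]
        return out

    def test_single_isomir_is_dominant(self, reference, annotator):
        loc = reference.loci[0]
        assigns = {"s1": [annotator.classify(CollapsedRead(loc.mature_seq, 5))]}
        iso, uniq = summarize_isomirs(assigns)
        assert iso["is_dominant"].sum() == 1
        assert uniq.loc[0, "unique_reads"] == 1

    def test_planted_mixture_dominant_is_majority_variant(
            self, reference, annotator):
        loc = reference.loci[0]
        variants = [
            (loc.mature_seq, 60),
            (loc.mature_seq[:-1], 30),
            (loc.precursor_seq[loc.mature_start - 1:loc.mature_end], 10),
        ]
        assigns = {"s1": [annotator.classify(CollapsedRead(s, c))
                          for s, c in variants]}
        iso, _ = summarize_isomirs(assigns)
        dom = iso[iso["is_dominant"]]
        assert len(dom) == 1
        assert dom.iloc[0]["seq"] == loc.mature_seq
        assert dom.iloc[0]["total"] == 60

    def test_canonical_only_simulation(self, noiseless_study):
        iso = noiseless_study["isomirs"]
        dom = iso[iso["is_dominant"]]
        assert dom["matches_canonical"].all()
        assert (dom["offset5"] == 0).all() and (dom["offset3"] == 0).all()

    def test_noisy_study_reports_unique_read_counts(self, noisy_study):
        uniq = noisy_study["unique_counts"]
        per_sample = uniq.groupby("sample")["unique_reads"].median()
        assert (per_sample >= 1).all()


class TestCountMatrix:
    def test_zero_noise_equals_truth(self, noiseless_study):
        truth = noiseless_study["truth"]
        counts = noiseless_study["counts"]
        aligned = counts.loc[truth.counts.index, truth.counts.columns]
        pd.testing.assert_frame_equal(aligned, truth.counts)

    def test_empty_library_column_retained(self, reference):
        assigns = {"empty_lib": []}
        counts, summary = build_count_matrix(assigns, reference)
        assert "empty_lib" in counts.columns
        assert (counts["empty_lib"] == 0).all()

    def test_star_rows_are_separate(self, noisy_study):
        counts = noisy_study["counts"]
        star_rows = [r for r in counts.index if r.endswith("*")]
        expected = [l.locus_id + "*" for l in noisy_study["reference"].loci
                    if l.star_start is not None]
        assert sorted(star_rows) == sorted(expected)

    def test_category_totals_conserve_qualified_reads(self, noisy_study):
        summary = noisy_study["summary"]
        for lib, stats in noisy_study["filter_stats"].items():
            assert summary[lib].sum() == stats.qualified
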