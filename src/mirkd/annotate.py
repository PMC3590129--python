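"""Hierarchical zero-mismatch classification of collapsed reads.

Every collapsed read is assigned exactly one category, in this order:

1. no exact genome hit (either strand)            -> ``unmapped``
2. exact hit in the ncRNA set                     -> ``ncrna``
3. genome hit inside an annotated precursor, on its strand, overlapping the
   mature or star arm with the seed (arm positions 2-8) fully contained and
   both end offsets within ``max_arm_offset``     -> ``known_mir``
4. inside a precursor but failing rule 3          -> ``precursor_other``
5. any other genome hit                           -> ``novel_candidate``

Reads matching two different miR loci are resolved to the locus with the
smallest ``|offset5| + |offset3|``; exact ties are flagged ``multi_mapper``
and excluded from the count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import revcomp
from .preprocess import CollapsedRead
from .reference import MiRLocus, ReferenceBundle

CATEGORIES = (
    "known_mir", "precursor_other", "ncrna", "novel_candidate", "unmapped",
    "multi_mapper",
)

DEFAULT_MAX_ARM_OFFSET = 3
SEED_SPAN = (1, 8)   # 0-based half-open: mature positions 2-8


class ExactIndex:
    """Exact substring lookup over a sequence collection, on both strands.

    ``query(s)`` returns every ``(seq_id, offset, strand)`` such that the
    forward-strand substring at that offset equals ``s`` (strand ``'+'``) or
    its reverse complement does (strand ``'-'``).  Backed by a k-mer
    dictionary with full verification, so results are identical to a naive
    scan.
    """

    def __init__(self, sequences: dict[str, str], k: int = 12):
        if not sequences:
            raise ValueError("cannot index an empty sequence collection")
        self.sequences = dict(sequences)
        self.k = k
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i:i + k], []).append((sid, i))

    def _forward_hits(self, q: str) -> list[tuple[str, int]]:
        n = len(q)
        if n < self.k:  # short queries fall back to a direct scan
            out = []
            for sid, seq in self.sequences.items():
                start = seq.find(q)
                while start != -1:
                    out.append((sid, start))
                    start = seq.find(q, start + 1)
            return out
        out = []
        for sid, i in self._kmers.get(q[:self.k], ()):
            if self.sequences[sid][i:i + n] == q:
                out.append((sid, i))
        return out

    def query(self, q: str, both_strands: bool = True) -> list[tuple[str, int, str]]:
        if not q:
            return []
        hits = [(sid, i, "+") for sid, i in self._forward_hits(q)]
        if both_strands:
            hits += [(sid, i, "-") for sid, i in self._forward_hits(revcomp(q))]
        return sorted(set(hits))


def build_exact_index(sequences: dict[str, str], k: int = 12) -> ExactIndex:
    return ExactIndex(sequences, k=k)


@dataclass(frozen=True)
class Assignment:
    """Classification of one collapsed read."""

    seq: str
    count: int
    category: str
    locus_id: str | None = None
    arm: str | None = None
    offset5: int | None = None
    offset3: int | None = None
    hit: tuple[str, int, str] | None = None   # first genome hit (chrom, pos, strand)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "known_mir" and (
            self.locus_id is None or self.arm is None
            or self.offset5 is None or self.offset3 is None
        ):
            raise ValueError("known_mir assignment requires locus, arm and offsets")


def _seed_interval(loc: MiRLocus, arm: str, mode: str) -> tuple[int, int]:
    a0, a1 = loc.arm_interval(arm)
    if mode == "five_prime":
        return a0 + SEED_SPAN[0], a0 + SEED_SPAN[1]
    if mode == "three_prime":   # 3'-anchored alternative (last 7 nt of the arm)
        return a1 - 7, a1
    raise ValueError(f"unknown seed_mode {mode!r}")


def classify_read(
    read: CollapsedRead,
    genome_index: ExactIndex,
    loci: list[MiRLocus],
    ncrna_index: ExactIndex | None,
    max_arm_offset: int = DEFAULT_MAX_ARM_OFFSET,
    seed_mode: str = "five_prime",
) -> Assignment:
    """Apply the hierarchical decision rules to one collapsed read."""
    seq, n = read.seq, len(read.seq)
    hits = genome_index.query(seq)
    if not hits:
        return Assignment(seq, read.count, "unmapped")
    if ncrna_index is not None and ncrna_index.query(seq):
        return Assignment(seq, read.count, "ncrna", hit=hits[0])

    candidates: set[tuple[str, str, int, int]] = set()
    in_precursor = False
    for chrom, pos, strand in hits:
        for loc in loci:
            if loc.chrom != chrom or strand != loc.strand:
                continue
            if not (loc.start <= pos and pos + n <= loc.end):
                continue
            in_precursor = True
            p0 = pos - loc.start if strand == "+" else loc.end - (pos + n)
            p1 = p0 + n
            arms = ["mature"] + (["star"] if loc.star_start is not None else [])
            for arm in arms:
                a0, a1 = loc.arm_interval(arm)
                o5, o3 = p0 - a0, p1 - a1
                if abs(o5) > max_arm_offset or abs(o3) > max_arm_offset:
                    continue
                s0, s1 = _seed_interval(loc, arm, seed_mode)
                if p0 <= s0 and s1 <= p1:
                    candidates.add((loc.locus_id, arm, o5, o3))
    if candidates:
        best = min(abs(o5) + abs(o3) for _, _, o5, o3 in candidates)
        winners = sorted(
            c for c in candidates if abs(c[2]) + abs(c[3]) == best
        )
        if len({(lid, arm) for lid, arm, _, _ in winners}) > 1:
            return Assignment(seq, read.count, "multi_mapper", hit=hits[0])
        lid, arm, o5, o3 = winners[0]
        return Assignment(seq, read.count, "known_mir", locus_id=lid, arm=arm,
                          offset5=o5, offset3=o3, hit=hits[0])
    if in_precursor:
        return Assignment(seq, read.count, "precursor_other", hit=hits[0])
    return Assignment(seq, read.count, "novel_candidate", hit=hits[0])


class Annotator:
    """Builds the genome and ncRNA indexes once and classifies libraries."""

    def __init__(self, ref: ReferenceBundle,
                 max_arm_offset: int = DEFAULT_MAX_ARM_OFFSET,
                 seed_mode: str = "five_prime"):
        self.ref = ref
        self.genome_index = ExactIndex(ref.genome)
        self.ncrna_index = (
            ExactIndex({r.id: r.seq for r in ref.ncrnas}) if ref.ncrnas else None
        )
        self.max_arm_offset = max_arm_offset
        self.seed_mode = seed_mode

    def classify(self, read: CollapsedRead) -> Assignment:
        return classify_read(read, self.genome_index, self.ref.loci,
                             self.ncrna_index, self.max_arm_offset, self.seed_mode)

    def annotate_library(self, collapsed: list[CollapsedRead]) -> list[Assignment]:
        return [self.classify(r) for r in collapsed]


def row_id(locus_id: str, arm: str) -> str:
    """Count-matrix row name; star arms carry the conventional '*' suffix."""
    return locus_id if arm == "mature" else locus_id + "*"


def summarize_isomirs(
    assignments_by_sample: dict[str, list[Assignment]],
    canonical: dict[tuple[str, str], str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IsomiR table plus per-(miR, sample) unique-read counts.

    One row per distinct (locus, arm, sequence); the dominant read of each
    (locus, arm) is the one with the highest summed count across samples,
    ties broken by lexicographically smallest sequence.
    """
    samples = list(assignments_by_sample)
    per_seq: dict[tuple[str, str, str], dict] = {}
    for sample, assigns in assignments_by_sample.items():
        for a in assigns:
            if a.category != "known_mir":
                continue
            key = (a.locus_id, a.arm, a.seq)
            rec = per_seq.setdefault(key, {
                "offset5": a.offset5, "offset3": a.offset3,
                **{s: 0 for s in samples},
            })
            rec[sample] += a.count
    rows = []
    for (lid, arm, seq), rec in sorted(per_seq.items()):
        total = sum(rec[s] for s in samples)
        canon = (canonical or {}).get((lid, arm))
        rows.append({
            "mir_id": row_id(lid, arm), "locus_id": lid, "arm": arm, "seq": seq,
            "offset5": rec["offset5"], "offset3": rec["offset3"], "total": total,
            "matches_canonical": (seq == canon) if canon is not None
            else (rec["offset5"] == 0 and rec["offset3"] == 0),
            **{s: rec[s] for s in samples},
        })
    iso = pd.DataFrame(rows)
    if not iso.empty:
        iso["is_dominant"] = False
        for _, grp in iso.groupby(["locus_id", "arm"]):
            nz = grp[grp["total"] > 0]
            if nz.empty:
                continue
            best = nz.sort_values(["total", "seq"],
                                  ascending=[False, True]).index[0]
            iso.loc[best, "is_dominant"] = True
        unique_rows = []
        for (lid, arm), grp in iso.groupby(["locus_id", "arm"]):
            for s in samples:
                unique_rows.append({
                    "mir_id": row_id(lid, arm), "sample": s,
                    "unique_reads": int((grp[s] > 0).sum()),
                })
        uniq = pd.DataFrame(unique_rows)
    else:
        uniq = pd.DataFrame(columns=["mir_id", "sample", "unique_reads"])
    return iso, uniq


def build_count_matrix(
    assignments_by_sample: dict[str, list[Assignment]],
    ref: ReferenceBundle,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miR × library count matrix plus a per-library category summary.

    Rows cover every annotated arm in the reference (mature and star as
    separate rows), so all-zero rows/columns are retained.  The summary's
    per-library category totals sum to the qualified read count.
    """
    row_ids = []
    for loc in ref.loci:
        row_ids.append(row_id(loc.locus_id, "mature"))
        if loc.star_start is not None:
            row_ids.append(row_id(loc.locus_id, "star"))
    samples = list(assignments_by_sample)
    counts = pd.DataFrame(0, index=row_ids, columns=samples, dtype=int)
    summary = pd.DataFrame(0, index=list(CATEGORIES), columns=samples, dtype=int)
    for sample, assigns in assignments_by_sample.items():
        for a in assigns:
            summary.loc[a.category, sample] += a.count
            if a.category == "known_mir":
                counts.loc[row_id(a.locus_id, a.arm), sample] += a.count
    counts.index.name = "mir_id"
    summary.index.name = "category"
    return counts, summary


def export_novel_candidates(
    assignments_by_sample: dict[str, list[Assignment]],
    path: str | Path,
) -> int:
    """Write novel-candidate reads as FASTA with genomic loci in the headers.

    These are the inputs an external hairpin-model tool would consume; the
    probabilistic novel-miR model itself is out of scope here.
    """
    pooled: dict[str, dict] = {}
    for assigns in assignments_by_sample.values():
        for a in assigns:
            if a.category != "novel_candidate":
                continue
            rec = pooled.setdefault(a.seq, {"count": 0, "hit": a.hit})
            rec["count"] += a.count
    with open(path, "w") as fh:
        for i, (seq, rec) in enumerate(sorted(pooled.items())):
            chrom, pos, strand = rec["hit"]
            fh.write(f">novel_{i:04d} count={rec['count']} "
                     f"locus={chrom}:{pos + 1}-{pos + len(seq)}({strand})\n{seq}\n")
    return len(pooled)
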