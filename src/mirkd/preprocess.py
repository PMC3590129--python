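"""Read preprocessing: 3' adapter trimming, length/quality filters, collapsing.

The only alignment in the pipeline where mismatches are tolerated is the
adapter search (all reference mapping downstream is exact).  A read whose
adapter cannot be located within the 2-mismatch budget is discarded as
"no adapter"; trimmed inserts are kept when 17–27 nt long (inclusive) with
every base at Phred ≥ 10, then collapsed to unique sequences with counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 27
DEFAULT_MIN_PHRED = 10
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_OVERLAP = 6


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with per-base integer Phred scores."""

    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError("quality and sequence lengths differ")
        if self.qual and not (0 <= min(self.qual) and max(self.qual) <= 60):
            raise ValueError("Phred scores out of [0, 60]")


@dataclass
class FilterStats:
    """Per-library tally of preprocessing outcomes; categories sum to total."""

    total: int = 0
    no_adapter: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    qualified: int = 0

    def check(self) -> None:
        parts = (self.no_adapter + self.too_short + self.too_long
                 + self.low_quality + self.qualified)
        if parts != self.total:
            raise AssertionError("FilterStats categories do not sum to total")

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total, "no_adapter": self.no_adapter,
            "too_short": self.too_short, "too_long": self.too_long,
            "low_quality": self.low_quality, "qualified": self.qualified,
        }


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence and its occurrence count in one library."""

    seq: str
    count: int


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ReadRecord | None:
    """Locate and remove the 3' adapter; ``None`` means no adapter found.

    Scans left to right for the first position where the adapter prefix
    aligns to the read suffix.  Full-length overlaps get the whole
    ``max_mismatch`` budget; terminal partial overlaps (length ``o`` with
    ``min_overlap <= o < len(adapter)``) get a pro-rated budget
    ``floor(max_mismatch * o / len(adapter))``.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = read.seq
    if not seq:
        return None
    alen = len(adapter)
    pos = _find_adapter(seq, adapter, alen, max_mismatch, min_overlap)
    if pos is None:
        return None
    return ReadRecord(read.read_id, seq[:pos], read.qual[:pos])


def _find_adapter(seq: str, adapter: str, alen: int,
                  max_mismatch: int, min_overlap: int) -> int | None:
    n = len(seq)
    for pos in range(0, n - min_overlap + 1):
        overlap = min(alen, n - pos)
        budget = (max_mismatch if overlap == alen
                  else (max_mismatch * overlap) // alen)
        window = seq[pos:pos + overlap]
        mism = 0
        for a, b in zip(window, adapter):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        if mism <= budget:
            return pos
    return None


def apply_filters(
    trimmed: Iterable[ReadRecord | None],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_phred: int = DEFAULT_MIN_PHRED,
    quality_mode: str = "per_base",
) -> tuple[list[ReadRecord], FilterStats]:
    """Apply the length window and quality rule with fixed precedence.

    Precedence per read: no_adapter > too_short > too_long > low_quality, so
    every read lands in exactly one category.  ``quality_mode`` is
    ``"per_base"`` (minimum per-base Phred over the insert, the default) or
    ``"mean"`` (mean insert Phred).
    """
    if quality_mode not in ("per_base", "mean"):
        raise ValueError(f"unknown quality_mode {quality_mode!r}")
    stats = FilterStats()
    kept: list[ReadRecord] = []
    for read in trimmed:
        stats.total += 1
        if read is None:
            stats.no_adapter += 1
        elif len(read.seq) < min_len:
            stats.too_short += 1
        elif len(read.seq) > max_len:
            stats.too_long += 1
        elif not _quality_ok(read.qual, min_phred, quality_mode):
            stats.low_quality += 1
        else:
            stats.qualified += 1
            kept.append(read)
    stats.check()
    return kept, stats


def _quality_ok(qual: Sequence[int], min_phred: int, mode: str) -> bool:
    if not qual:
        return False
    if mode == "mean":
        return sum(qual) / len(qual) >= min_phred
    return min(qual) >= min_phred


def collapse_reads(qualified: Iterable[ReadRecord | str]) -> list[CollapsedRead]:
    """Collapse qualified inserts to unique sequences with counts.

    Sorted by descending count, ties broken lexicographically by sequence,
    so output order is deterministic.
    """
    counts = Counter(r if isinstance(r, str) else r.seq for r in qualified)
    return [
        CollapsedRead(seq=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a Phred+33 FASTQ file into ReadRecords."""
    return [
        ReadRecord(rec.id, str(rec.seq),
                   tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def preprocess_fastq(
    path: str | Path,
    adapter: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_phred: int = DEFAULT_MIN_PHRED,
    quality_mode: str = "per_base",
) -> tuple[list[CollapsedRead], FilterStats]:
    """Run trim → filter → collapse over one FASTQ library."""
    reads = read_fastq(path)
    trimmed = (trim_adapter(r, adapter, max_mismatch, min_overlap) for r in reads)
    kept, stats = apply_filters(trimmed, min_len, max_len, min_phred, quality_mode)
    return collapse_reads(kept), stats
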