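"""End-to-end glue: simulated FASTQ libraries → count matrix → DE results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import preprocess as pp
from .annotate import Annotator, Assignment, build_count_matrix, summarize_isomirs
from .diffexp import DEResults, NegativeBinomialDE
from .reference import ReferenceBundle
from .simulate import SimulationConfig, TruthTable, simulate_study


def preprocess_libraries(
    fastq_paths: dict[str, Path], adapter: str, **filter_kwargs,
) -> tuple[dict[str, list[pp.CollapsedRead]], dict[str, pp.FilterStats]]:
    """Trim/filter/collapse every library FASTQ."""
    collapsed, stats = {}, {}
    for lib, path in fastq_paths.items():
        collapsed[lib], stats[lib] = pp.preprocess_fastq(path, adapter,
                                                         **filter_kwargs)
    return collapsed, stats


def annotate_libraries(
    collapsed: dict[str, list[pp.CollapsedRead]], ref: ReferenceBundle,
    **annot_kwargs,
) -> dict[str, list[Assignment]]:
    annotator = Annotator(ref, **annot_kwargs)
    return {lib: annotator.annotate_library(reads)
            for lib, reads in collapsed.items()}


def run_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, object]:
    """Simulate a study, preprocess and annotate it, and fit the DE model.

    Returns the reference, truth, filter stats, count matrix, isomiR table
    and fitted :class:`DEResults` in one dictionary.
    """
    out = Path(out_dir)
    sim = simulate_study(config, out)
    ref: ReferenceBundle = sim["reference"]
    truth: TruthTable = sim["truth"]
    fastqs = {lib: p["fastq"] for lib, p in sim["fastq_paths"].items()}
    collapsed, stats = preprocess_libraries(fastqs, config.adapter_seq)
    assignments = annotate_libraries(collapsed, ref)
    counts, summary = build_count_matrix(assignments, ref)
    canonical = {}
    for loc in ref.loci:
        canonical[(loc.locus_id, "mature")] = loc.mature_seq
        if loc.star_seq is not None:
            canonical[(loc.locus_id, "star")] = loc.star_seq
    isomirs, unique_counts = summarize_isomirs(assignments, canonical)
    counts.to_csv(out / "count_matrix.tsv", sep="\t")
    summary.to_csv(out / "category_summary.tsv", sep="\t")
    if not isomirs.empty:
        isomirs.to_csv(out / "isomirs.tsv", sep="\t", index=False)
    results: DEResults | None = None
    if truth.samples["condition"].nunique() == 2:
        model = NegativeBinomialDE.from_dataframe(counts, truth.samples)
        results = model.fit(use_pseudo_reference=True)
        results.to_tsv(out / "diffexp.tsv")
    return {
        "out_dir": out,
        "reference": ref, "truth": truth, "filter_stats": stats,
        "assignments": assignments, "counts": counts, "summary": summary,
        "isomirs": isomirs, "unique_counts": unique_counts, "results": results,
    }


def load_count_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
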