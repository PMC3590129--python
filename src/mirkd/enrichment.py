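"""Pathway over-representation of predicted miR targets.

Targets are taken from a precomputed miR → gene score table (miTG scores,
kept at score ≥ 0.7 by default), pooled into a union set over the queried
miRs, intersected with the pathway-database gene universe, and scored per
pathway with a one-sided (upper-tail hypergeometric) Fisher's exact test.
No multiple-testing correction is applied by default; raw p-values are
reported, with BH adjustment available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import pandas as pd
from scipy import stats

DEFAULT_MITG_THRESHOLD = 0.7
DEFAULT_MIN_PATHWAY_GENES = 10
_EXACT_UNIVERSE_LIMIT = 2000


def load_target_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (mir_id, gene_id, mitg_score) records."""
    df = pd.read_csv(path, sep="\t")
    required = {"mir_id", "gene_id", "mitg_score"}
    if not required <= set(df.columns):
        raise ValueError(f"target table needs columns {sorted(required)}")
    if df.duplicated(["mir_id", "gene_id"]).any():
        raise ValueError("duplicate (mir_id, gene_id) pairs in target table")
    return df


def load_pathways(path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets from GMT or two-column TSV."""
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            pathways[fields[0]] = {g for g in fields[2:] if g}
    else:
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:2])
        for pid, grp in df.groupby(cols[0]):
            pathways[str(pid)] = set(grp[cols[1]].astype(str))
    if any(not genes for genes in pathways.values()):
        raise ValueError("empty pathway gene set")
    return pathways


def union_target_set(mir_ids, table: pd.DataFrame,
                     threshold: float = DEFAULT_MITG_THRESHOLD) -> set[str]:
    """Union of predicted targets at miTG score ≥ threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    present = set(table["mir_id"])
    missing = [m for m in mir_ids if m not in present]
    if missing:
        warnings.warn(f"miRs absent from target table: {missing}")
    sel = table[table["mir_id"].isin(set(mir_ids))
                & (table["mitg_score"] >= threshold)]
    return set(sel["gene_id"])


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation test."""

    pathway_id: str
    n_universe: int
    n_pathway: int
    n_targets_in_universe: int
    n_overlap: int
    p: float
    overlap_genes: tuple[str, ...] = ()


def _hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, n, N), exactly for small universes."""
    if M <= _EXACT_UNIVERSE_LIMIT:
        denom = comb(M, N)
        total = Fraction(0)
        for x in range(k, min(n, N) + 1):
            total += Fraction(comb(n, x) * comb(M - n, N - x), denom)
        return float(min(total, Fraction(1)))
    return float(min(stats.hypergeom.sf(k - 1, M, n, N), 1.0))


def fisher_pathway_test(targets: set[str], pathway: set[str],
                        universe: set[str]) -> EnrichmentResult:
    """One-sided Fisher's exact test of target/pathway overlap.

    Targets are intersected with the universe before testing; the p-value is
    the upper hypergeometric tail P(X ≥ observed overlap).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not pathway <= universe:
        raise ValueError("pathway genes must be a subset of the universe")
    targets_u = targets & universe
    overlap = sorted(targets_u & pathway)
    p = _hypergeom_upper_tail(len(overlap), len(universe),
                              len(pathway), len(targets_u))
    return EnrichmentResult(
        pathway_id="", n_universe=len(universe), n_pathway=len(pathway),
        n_targets_in_universe=len(targets_u), n_overlap=len(overlap),
        p=p, overlap_genes=tuple(overlap),
    )


def run_enrichment(mir_ids, table: pd.DataFrame,
                   pathway_db: dict[str, set[str]],
                   min_pathway_genes: int = DEFAULT_MIN_PATHWAY_GENES,
                   threshold: float = DEFAULT_MITG_THRESHOLD,
                   bh: bool = False) -> pd.DataFrame:
    """Test every sufficiently large pathway; rank ascending by p.

    Pathways with fewer than ``min_pathway_genes`` genes are excluded before
    testing.  The universe is the union of all pathway genes (including the
    filtered ones' — the database defines the annotatable gene space).
    """
    universe = set().union(*pathway_db.values()) if pathway_db else set()
    targets = union_target_set(mir_ids, table, threshold)
    kept = {pid: genes for pid, genes in pathway_db.items()
            if len(genes) >= min_pathway_genes}
    if not kept:
        warnings.warn("no pathway passes the minimum-size filter")
        return pd.DataFrame(columns=[
            "pathway_id", "n_universe", "n_pathway", "n_targets_in_universe",
            "n_overlap", "p", "overlap_genes"])
    rows = []
    for pid in sorted(kept):
        res = fisher_pathway_test(targets, kept[pid], universe)
        rows.append({
            "pathway_id": pid, "n_universe": res.n_universe,
            "n_pathway": res.n_pathway,
            "n_targets_in_universe": res.n_targets_in_universe,
            "n_overlap": res.n_overlap, "p": res.p,
            "overlap_genes": ";".join(res.overlap_genes),
        })
    out = pd.DataFrame(rows)
    if bh:
        from .diffexp import bh_adjust
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "pathway_id"]).reset_index(drop=True)
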