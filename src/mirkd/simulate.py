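"""Synthetic study generator: reference bundle, ground-truth counts, FASTQ.

Emulates a paired-design whole-blood small-RNA study at desk scale: a ~50 kb
two-chromosome mini genome carrying miR precursors and ncRNA contaminants,
negative-binomial per-library counts with planted fold changes between the
acute and convalescent condition, 22-nt-modal mature sequences with 5'/3'
isomiR offset variation, a ligated 3' adapter, and configurable fractions of
ncRNA, unmappable, out-of-window and adapter-free reads.  Everything is a
deterministic function of the configuration (including its seed), so two
runs of the same configuration are byte-identical, and per-read truth
sidecars let every downstream stage be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import phred_to_ascii, random_dna, revcomp
from .annotate import ExactIndex
from .preprocess import (
    DEFAULT_MAX_MISMATCH, DEFAULT_MIN_OVERLAP, DEFAULT_MIN_PHRED, _find_adapter,
)
from .reference import MiRLocus, NcRNARecord, ReferenceBundle

DEFAULT_ADAPTER = "CCGAATAATGCGTTCGCTCTA"  # 21 nt, screened for self-similarity

# 3' variation dominates 5' variation 4:1, matching the 3'-terminal isomiR
# heterogeneity seen in small-RNA libraries.
DEFAULT_OFFSET_PROBS: dict[tuple[int, int], float] = {}
for _o5, _p5 in ((-1, 0.05), (0, 0.90), (1, 0.05)):
    for _o3, _p3 in ((-2, 0.06), (-1, 0.14), (0, 0.60), (1, 0.14), (2, 0.06)):
        DEFAULT_OFFSET_PROBS[(_o5, _o3)] = _p5 * _p3

_MATURE_LENGTHS = (21, 22, 23)
_MATURE_LENGTH_PROBS = (0.25, 0.50, 0.25)
_FLANK5, _LOOP, _FLANK3 = 8, 15, 8


@dataclass(frozen=True)
class QualityModel:
    """Per-base Phred ~ clamped discretized normal, plus a low-quality spike.

    ``low_quality_fraction`` of reads carry one sub-Q10 base inside the
    insert, exercising the quality filter.
    """

    mean: float = 35.0
    sd: float = 4.0
    qmin: int = 2
    qmax: int = 40
    low_quality_fraction: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic generator."""

    n_pairs: int = 12
    n_loci: int = 50
    library_size: int = 2000
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    dispersion: float | dict[str, float] = 0.1
    isomir_offset_probs: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_PROBS))
    adapter_seq: str = DEFAULT_ADAPTER
    read_length: int = 36
    quality_model: QualityModel = field(default_factory=QualityModel)
    ncrna_fraction: float = 0.10
    junk_fraction: float = 0.03
    short_long_fraction: float = 0.04
    no_adapter_fraction: float = 0.05
    star_fraction: float = 0.4
    n_ncrnas: int = 15
    genome_size: int = 50_000
    n_chroms: int = 2
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.ncrna_fraction, self.junk_fraction,
                 self.short_long_fraction, self.no_adapter_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("noise fractions must lie in [0,1] and sum to < 1")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 subject pairs")
        disps = (self.dispersion.values() if isinstance(self.dispersion, dict)
                 else [self.dispersion])
        if any(a < 0 for a in disps):
            raise ValueError("dispersion must be >= 0")
        total_p = sum(self.isomir_offset_probs.values())
        if not np.isclose(total_p, 1.0):
            raise ValueError("isomiR offset probabilities must sum to 1")

    @property
    def mir_fraction(self) -> float:
        return 1.0 - (self.ncrna_fraction + self.junk_fraction
                      + self.short_long_fraction + self.no_adapter_fraction)

    def noiseless(self) -> "SimulationConfig":
        """Copy with every noise channel and isomiR variation switched off."""
        return replace(
            self, ncrna_fraction=0.0, junk_fraction=0.0,
            short_long_fraction=0.0, no_adapter_fraction=0.0,
            isomir_offset_probs={(0, 0): 1.0},
            quality_model=replace(self.quality_model, low_quality_fraction=0.0),
        )


@dataclass
class TruthTable:
    """Ground truth for one simulated study."""

    counts: pd.DataFrame         # rows = mir_id (locus or locus*), cols = libraries
    samples: pd.DataFrame        # library, condition, pair_id, size_factor
    planted: pd.Series           # per-row planted log2 fold change
    is_de: pd.Series             # per-row planted DE flag

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("truth counts must be nonnegative")
        if self.samples["pair_id"].notna().any():
            per_pair = self.samples.dropna(subset=["pair_id"]).groupby("pair_id")
            for pid, grp in per_pair:
                if len(grp) != 2 or grp["condition"].nunique() != 2:
                    raise ValueError(f"pair {pid} is not one library per condition")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "truth_counts.tsv", sep="\t")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        pd.DataFrame({
            "mir_id": self.counts.index,
            "planted_log2fc": self.planted.values,
            "is_de": self.is_de.values,
        }).to_csv(out / "truth_flags.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "TruthTable":
        out = Path(out_dir)
        counts = pd.read_csv(out / "truth_counts.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(out / "samples.tsv", sep="\t")
        flags = pd.read_csv(out / "truth_flags.tsv", sep="\t", index_col=0)
        return cls(counts=counts, samples=samples,
                   planted=flags["planted_log2fc"], is_de=flags["is_de"])


# --------------------------------------------------------------------------
# reference construction


def build_reference(config: SimulationConfig) -> ReferenceBundle:
    """Assemble the mini genome, miR loci and ncRNA records.

    Each precursor and ncRNA is embedded verbatim (precursors reverse-
    complemented on the minus strand) at non-overlapping coordinates with
    random flanking DNA; the build is retried with a fresh internal stream
    in the astronomically unlikely event that an annotated arm sequence
    recurs elsewhere in the genome.
    """
    if config.n_loci < 10:
        raise ValueError("at least 10 miR loci are required")
    for attempt in range(5):
        rng = np.random.default_rng([config.seed % (2**31), 17, attempt])
        ref = _try_build_reference(config, rng)
        if _arms_unique(ref):
            return ref
    raise RuntimeError("could not build a collision-free reference")


def _try_build_reference(config, rng) -> ReferenceBundle:
    loci_proto = []
    arm_seqs: set[str] = set()
    for i in range(config.n_loci):
        mlen = rng.choice(_MATURE_LENGTHS, p=_MATURE_LENGTH_PROBS)
        has_star = rng.random() < config.star_fraction
        while True:
            mature = random_dna(rng, int(mlen))
            star = random_dna(rng, int(mlen))
            if mature not in arm_seqs and star not in arm_seqs and mature != star:
                break
        arm_seqs.update({mature, star} if has_star else {mature})
        pre = (random_dna(rng, _FLANK5) + mature + random_dna(rng, _LOOP)
               + star + random_dna(rng, _FLANK3))
        m0 = _FLANK5
        s0 = _FLANK5 + int(mlen) + _LOOP
        loci_proto.append({
            "locus_id": f"syn-mir-{i + 1:03d}", "seq": pre,
            "mature": (m0, m0 + int(mlen)),
            "star": (s0, s0 + int(mlen)) if has_star else None,
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    ncrna_proto = []
    classes = sorted(("lincRNA", "rRNA", "snRNA", "snoRNA", "tRNA"))
    for i in range(config.n_ncrnas):
        length = int(rng.integers(80, 201))
        ncrna_proto.append({
            "id": f"syn-nc-{i + 1:03d}",
            "rna_class": classes[i % len(classes)],
            "seq": random_dna(rng, length),
        })

    # interleave elements and distribute them round-robin over chromosomes
    order = rng.permutation(len(loci_proto) + len(ncrna_proto))
    pool = [("mir", p) for p in loci_proto] + [("nc", p) for p in ncrna_proto]
    elements = [pool[k] for k in order]

    chrom_len = config.genome_size // config.n_chroms
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_names}
    loci: list[MiRLocus] = []
    ncrnas: list[NcRNARecord] = []
    for k, (kind, proto) in enumerate(elements):
        chrom = chrom_names[k % config.n_chroms]
        gap = int(rng.integers(120, 400))
        seq = proto["seq"]
        start = chrom_pos[chrom] + gap
        end = start + len(seq)
        if end > chrom_len - 120:
            raise ValueError(
                "requested loci exceed mini-genome capacity; "
                "increase genome_size or reduce n_loci/n_ncrnas")
        chrom_parts[chrom].append(random_dna(rng, gap))
        if kind == "mir":
            embedded = seq if proto["strand"] == "+" else revcomp(seq)
            chrom_parts[chrom].append(embedded)
            star = proto["star"] or (None, None)
            loci.append(MiRLocus(
                locus_id=proto["locus_id"], chrom=chrom, start=start, end=end,
                strand=proto["strand"], precursor_seq=seq,
                mature_start=proto["mature"][0], mature_end=proto["mature"][1],
                star_start=star[0], star_end=star[1],
            ))
        else:
            chrom_parts[chrom].append(seq)
            ncrnas.append(NcRNARecord(
                id=proto["id"], rna_class=proto["rna_class"], seq=seq,
                chrom=chrom, start=start, end=end,
            ))
        chrom_pos[chrom] = end
    genome = {}
    for chrom in chrom_names:
        pad = chrom_len - chrom_pos[chrom]
        genome[chrom] = "".join(chrom_parts[chrom]) + random_dna(rng, pad)
    return ReferenceBundle(genome=genome, loci=loci, ncrnas=ncrnas)


def _arms_unique(ref: ReferenceBundle) -> bool:
    index = ExactIndex(ref.genome)
    for loc in ref.loci:
        for arm_seq in (loc.mature_seq, loc.star_seq):
            if arm_seq is not None and len(index.query(arm_seq)) != 1:
                return False
    return True


# --------------------------------------------------------------------------
# truth counts


def _row_ids(ref: ReferenceBundle) -> list[tuple[str, str, str]]:
    rows = []
    for loc in ref.loci:
        rows.append((loc.locus_id, "mature", loc.locus_id))
        if loc.star_start is not None:
            rows.append((loc.locus_id + "*", "star", loc.locus_id))
    return rows


def simulate_truth_counts(ref: ReferenceBundle,
                          config: SimulationConfig) -> TruthTable:
    """Draw per-(miR, library) true counts from the NB study model.

    Count for row i in library j is negative binomial with mean
    ``s_j * q_i(condition_j)`` and variance ``mean + alpha * mean**2``;
    acute means equal convalescent means times ``2**planted_log2fc``.
    ``alpha == 0`` degenerates to Poisson.
    """
    rng = np.random.default_rng([config.seed % (2**31), 29])
    rows = _row_ids(ref)
    unknown = set(config.planted_log2fc) - {r[0] for r in rows} - {r[2] for r in rows}
    if unknown:
        raise ValueError(f"planted_log2fc keys not in reference: {sorted(unknown)}")

    w = rng.lognormal(mean=0.0, sigma=1.2, size=len(rows))
    w[[i for i, r in enumerate(rows) if r[1] == "star"]] *= 0.12
    base = w / w.sum() * config.library_size * config.mir_fraction

    n = config.n_pairs
    if config.paired:
        libs = [f"acute_{i + 1:02d}" for i in range(n)] \
             + [f"conv_{i + 1:02d}" for i in range(n)]
        conds = ["acute"] * n + ["convalescent"] * n
        pairs = [f"P{i + 1:02d}" for i in range(n)] * 2
    else:
        libs = [f"acute_{i + 1:02d}" for i in range(n)] \
             + [f"control_{i + 1:02d}" for i in range(n)]
        conds = ["acute"] * n + ["control"] * n
        pairs = [None] * (2 * n)
    s = rng.lognormal(mean=0.0, sigma=0.15, size=2 * n)

    lfc = np.array([
        config.planted_log2fc.get(rid, config.planted_log2fc.get(lid, 0.0))
        for rid, _, lid in rows
    ])
    alpha = np.array([
        config.dispersion.get(rid, config.dispersion.get(lid, 0.0))
        if isinstance(config.dispersion, dict) else config.dispersion
        for rid, _, lid in rows
    ])

    counts = np.zeros((len(rows), 2 * n), dtype=int)
    for j, cond in enumerate(conds):
        mu = s[j] * base * np.where(cond == "acute", 2.0 ** lfc, 1.0)
        lam = np.where(
            alpha > 0,
            rng.gamma(np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0),
                      np.maximum(alpha, 1e-12) * mu),
            mu,
        )
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=[r[0] for r in rows], columns=libs)
    counts_df.index.name = "mir_id"
    samples = pd.DataFrame({
        "library": libs, "condition": conds, "pair_id": pairs, "size_factor": s,
    })
    planted = pd.Series(lfc, index=counts_df.index, name="planted_log2fc")
    return TruthTable(counts=counts_df, samples=samples, planted=planted,
                      is_de=(planted != 0.0).rename("is_de"))


# --------------------------------------------------------------------------
# FASTQ synthesis


def synthesize_fastq(truth: TruthTable, ref: ReferenceBundle,
                     config: SimulationConfig,
                     out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write one FASTQ + one per-read truth sidecar TSV per library.

    Each counted read is its arm sequence modified by an isomiR offset, with
    the 3' adapter appended, padded with random bases and reported at the
    instrument read length.  Noise reads (ncRNA fragments, unmappable junk,
    out-of-window inserts, adapter-free reads) are drawn at the configured
    rates; realized per-category counts are exactly what the sidecar
    records.  The sidecar's ``fate`` column is the preprocessing outcome
    implied by the documented filter precedence.
    """
    _validate_offsets(ref, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arm_of = {}
    for loc in ref.loci:
        arm_of[loc.locus_id] = (loc, "mature")
        if loc.star_start is not None:
            arm_of[loc.locus_id + "*"] = (loc, "star")
    genome_index = ExactIndex(ref.genome)
    offsets = sorted(config.isomir_offset_probs)
    probs = np.array([config.isomir_offset_probs[o] for o in offsets])
    probs = probs / probs.sum()

    paths: dict[str, dict[str, Path]] = {}
    for j, lib in enumerate(truth.samples["library"]):
        rng = np.random.default_rng([config.seed % (2**31), 43, j])
        s_j = float(truth.samples["size_factor"].iloc[j])
        records: list[tuple[str, str, str, str, int, int]] = []
        # (insert, category, locus row id, arm, offset5, offset3)
        for rid in truth.counts.index:
            c = int(truth.counts.loc[rid, lib])
            if c == 0:
                continue
            loc, arm = arm_of[rid]
            a0, a1 = loc.arm_interval(arm)
            picks = rng.choice(len(offsets), size=c, p=probs)
            for k in picks:
                o5, o3 = offsets[k]
                insert = loc.precursor_seq[a0 + o5:a1 + o3]
                records.append((insert, "mir", rid, arm, o5, o3))
        n_ncrna = rng.poisson(config.library_size * s_j * config.ncrna_fraction)
        n_junk = rng.poisson(config.library_size * s_j * config.junk_fraction)
        n_sl = rng.poisson(config.library_size * s_j * config.short_long_fraction)
        n_short = rng.binomial(n_sl, 0.5) if n_sl else 0
        n_long = n_sl - n_short
        n_noad = rng.poisson(config.library_size * s_j * config.no_adapter_fraction)
        records += _draw_ncrna_reads(rng, ref, config, int(n_ncrna))
        records += _draw_junk_reads(rng, genome_index, config, int(n_junk))
        records += _draw_window_violations(rng, config, int(n_short), int(n_long))
        records += _draw_no_adapter_reads(rng, config, int(n_noad))

        order = rng.permutation(len(records))
        fastq_path = out / f"{lib}.fastq"
        sidecar_path = out / f"{lib}.truth.tsv"
        qm = config.quality_model
        side_rows = []
        with open(fastq_path, "w") as fq:
            for idx, k in enumerate(order):
                insert, cat, rid, arm, o5, o3 = records[k]
                read_id = f"{lib}_r{idx:06d}"
                if cat == "no_adapter":
                    seq = insert
                    ilen = config.read_length
                else:
                    seq = _compose(insert, config, rng)
                    ilen = len(insert)
                qual = np.clip(
                    np.rint(rng.normal(qm.mean, qm.sd, size=len(seq))),
                    qm.qmin, qm.qmax,
                ).astype(int)
                if qm.low_quality_fraction and rng.random() < qm.low_quality_fraction:
                    pos = int(rng.integers(0, max(ilen, 1)))
                    qual[pos] = int(rng.integers(qm.qmin, DEFAULT_MIN_PHRED))
                fate = _fate(cat, ilen, qual)
                fq.write(f"@{read_id}\n{seq}\n+\n{phred_to_ascii(qual)}\n")
                side_rows.append({
                    "read_id": read_id, "category": cat, "mir_id": rid,
                    "arm": arm, "offset5": o5, "offset3": o3,
                    "insert_len": ilen, "fate": fate,
                })
        pd.DataFrame(
            side_rows,
            columns=["read_id", "category", "mir_id", "arm",
                     "offset5", "offset3", "insert_len", "fate"],
        ).to_csv(sidecar_path, sep="\t", index=False)
        paths[lib] = {"fastq": fastq_path, "sidecar": sidecar_path}
    return paths


def _validate_offsets(ref: ReferenceBundle, config: SimulationConfig) -> None:
    for loc in ref.loci:
        arms = ["mature"] + (["star"] if loc.star_start is not None else [])
        for arm in arms:
            a0, a1 = loc.arm_interval(arm)
            for (o5, o3), p in config.isomir_offset_probs.items():
                if p <= 0:
                    continue
                if abs(o5) >= a1 - a0 or abs(o3) >= a1 - a0:
                    raise ValueError("isomiR offset exceeds mature length")
                if a0 + o5 < 0 or a1 + o3 > len(loc.precursor_seq) \
                        or a0 + o5 >= a1 + o3:
                    raise ValueError(
                        f"isomiR offset ({o5},{o3}) leaves precursor of "
                        f"{loc.locus_id}")


def _compose(insert: str, config: SimulationConfig, rng) -> str:
    full = insert + config.adapter_seq
    if len(full) < config.read_length:
        full += random_dna(rng, config.read_length - len(full))
    return full[:config.read_length]


def _trims_at(seq: str, config: SimulationConfig, expected: int) -> bool:
    pos = _find_adapter(seq, config.adapter_seq, len(config.adapter_seq),
                        DEFAULT_MAX_MISMATCH, DEFAULT_MIN_OVERLAP)
    return pos == expected


def _fate(cat: str, insert_len: int, qual: np.ndarray) -> str:
    if cat == "no_adapter":
        return "no_adapter"
    if insert_len < 17:
        return "too_short"
    if insert_len > 27:
        return "too_long"
    if int(qual[:insert_len].min()) < DEFAULT_MIN_PHRED:
        return "low_quality"
    return "qualified"


def _draw_ncrna_reads(rng, ref, config, n):
    out = []
    if n and not ref.ncrnas:
        raise ValueError("ncrna_fraction > 0 but reference has no ncRNAs")
    while len(out) < n:
        rec = ref.ncrnas[int(rng.integers(0, len(ref.ncrnas)))]
        length = int(rng.integers(17, 28))
        start = int(rng.integers(0, len(rec.seq) - length + 1))
        frag = rec.seq[start:start + length]
        if _trims_at(_compose(frag, config, rng), config, length):
            out.append((frag, "ncrna", rec.id, "", 0, 0))
    return out


def _draw_junk_reads(rng, genome_index, config, n):
    out = []
    while len(out) < n:
        length = int(rng.integers(17, 28))
        frag = random_dna(rng, length)
        if genome_index.query(frag):
            continue
        if _trims_at(_compose(frag, config, rng), config, length):
            out.append((frag, "junk", "", "", 0, 0))
    return out


def _draw_window_violations(rng, config, n_short, n_long):
    out = []
    while len([r for r in out if r[1] == "short"]) < n_short:
        length = int(rng.integers(8, 17))
        out.append((random_dna(rng, length), "short", "", "", 0, 0))
    while len([r for r in out if r[1] == "long"]) < n_long:
        length = int(rng.integers(28, 31))
        frag = random_dna(rng, length)
        if _trims_at(_compose(frag, config, rng), config, length):
            out.append((frag, "long", "", "", 0, 0))
    return out


def _draw_no_adapter_reads(rng, config, n):
    out = []
    while len(out) < n:
        seq = random_dna(rng, config.read_length)
        pos = _find_adapter(seq, config.adapter_seq, len(config.adapter_seq),
                            DEFAULT_MAX_MISMATCH, DEFAULT_MIN_OVERLAP)
        if pos is None:
            out.append((seq, "no_adapter", "", "", 0, 0))
    return out


def simulate_study(config: SimulationConfig,
                   out_dir: str | Path) -> dict[str, object]:
    """Run the whole generator: reference + truth + per-library FASTQ."""
    out = Path(out_dir)
    ref = build_reference(config)
    ref_paths = ref.write(out / "reference")
    truth = simulate_truth_counts(ref, config)
    truth.write(out / "truth")
    fastq_paths = synthesize_fastq(truth, ref, config, out / "reads")
    return {"reference": ref, "truth": truth,
            "reference_paths": ref_paths, "fastq_paths": fastq_paths}
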