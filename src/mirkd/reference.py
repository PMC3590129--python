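"""Reference data model: miR loci, ncRNA records and their FASTA/GFF3 round trip.

A :class:`MiRLocus` is the unit of annotation: a precursor hairpin placed on a
(mini) genome, carrying a mature arm and optionally a star arm.  Intervals are
0-based half-open internally; the GFF3 writer/reader converts to and from the
miRBase dialect (1-based inclusive, features ``miRNA_primary_transcript`` and
``miRNA``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

NCRNA_CLASSES = frozenset({"lincRNA", "rRNA", "snRNA", "snoRNA", "tRNA"})

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


@dataclass(frozen=True)
class MiRLocus:
    """A miR precursor with annotated mature (and optional star) intervals.

    ``precursor_seq`` is stored in transcript (5'→3') orientation; on the
    minus strand the genome holds its reverse complement.  ``mature_start`` /
    ``mature_end`` (and the star pair) are 0-based half-open offsets *within*
    the precursor, in transcript orientation.
    """

    locus_id: str
    chrom: str
    start: int          # genomic, 0-based half-open
    end: int
    strand: str         # '+' or '-'
    precursor_seq: str
    mature_start: int
    mature_end: int
    star_start: int | None = None
    star_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.precursor_seq):
            raise ValueError("precursor interval does not match sequence length")
        if set(self.precursor_seq) - set("ACGT"):
            raise ValueError("precursor sequence must be over {A,C,G,T}")
        if not (0 <= self.mature_start < self.mature_end <= len(self.precursor_seq)):
            raise ValueError("mature interval outside precursor")
        if self.star_start is not None:
            if self.star_end is None:
                raise ValueError("star_end missing")
            if not (0 <= self.star_start < self.star_end <= len(self.precursor_seq)):
                raise ValueError("star interval outside precursor")
            if self.star_start < self.mature_end and self.mature_start < self.star_end:
                raise ValueError("mature and star intervals overlap")

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_start:self.mature_end]

    @property
    def star_seq(self) -> str | None:
        if self.star_start is None:
            return None
        return self.precursor_seq[self.star_start:self.star_end]

    def arm_interval(self, arm: str) -> tuple[int, int]:
        """Precursor-internal interval of ``arm`` ('mature' or 'star')."""
        if arm == "mature":
            return self.mature_start, self.mature_end
        if arm == "star":
            if self.star_start is None:
                raise ValueError(f"{self.locus_id} has no star arm")
            return self.star_start, self.star_end
        raise ValueError(f"unknown arm {arm!r}")

    def genomic_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Map a precursor-internal interval to genomic coordinates."""
        if self.strand == "+":
            return self.start + p_start, self.start + p_end
        return self.end - p_end, self.end - p_start


@dataclass(frozen=True)
class NcRNARecord:
    """A non-miR small RNA contaminant (lincRNA/rRNA/snRNA/snoRNA/tRNA)."""

    id: str
    rna_class: str
    seq: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.rna_class not in NCRNA_CLASSES:
            raise ValueError(f"unknown ncRNA class {self.rna_class!r}")
        if not self.seq:
            raise ValueError("empty ncRNA sequence")


@dataclass
class ReferenceBundle:
    """Mini genome plus its miR and ncRNA annotation."""

    genome: dict[str, str]
    loci: list[MiRLocus]
    ncrnas: list[NcRNARecord]

    def locus(self, locus_id: str) -> MiRLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def extract(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genome substring in transcript orientation."""
        s = self.genome[chrom][start:end]
        return s if strand == "+" else revcomp(s)

    # ------------------------------------------------------------------ I/O

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write genome.fa, mir.gff3, hairpin.fa, mature.fa and ncrna.fa."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gff3": out / "mir.gff3",
            "hairpin": out / "hairpin.fa",
            "mature": out / "mature.fa",
            "ncrna": out / "ncrna.fa",
        }
        _write_fasta(paths["genome"], [(c, s) for c, s in self.genome.items()])
        _write_fasta(paths["hairpin"], [(l.locus_id, l.precursor_seq) for l in self.loci])
        mature_records = []
        for l in self.loci:
            mature_records.append((l.locus_id, l.mature_seq))
            if l.star_seq is not None:
                mature_records.append((l.locus_id + "*", l.star_seq))
        _write_fasta(paths["mature"], mature_records)
        _write_fasta(
            paths["ncrna"],
            [(f"{r.id} class={r.rna_class}", r.seq) for r in self.ncrnas],
        )
        paths["gff3"].write_text(self.to_gff3())
        return paths

    def to_gff3(self) -> str:
        """miRBase-dialect GFF3 (1-based inclusive coordinates)."""
        buf = io.StringIO()
        buf.write("##gff-version 3\n")
        for loc in sorted(self.loci, key=lambda l: (l.chrom, l.start)):
            buf.write(_gff_line(
                loc.chrom, "miRNA_primary_transcript", loc.start, loc.end,
                loc.strand, f"ID={loc.locus_id};Name={loc.locus_id}",
            ))
            for arm, suffix in (("mature", ""), ("star", "*")):
                if arm == "star" and loc.star_start is None:
                    continue
                g0, g1 = loc.genomic_interval(*loc.arm_interval(arm))
                buf.write(_gff_line(
                    loc.chrom, "miRNA", g0, g1, loc.strand,
                    f"ID={loc.locus_id}_{arm};Name={loc.locus_id}{suffix};"
                    f"Derives_from={loc.locus_id}",
                ))
        return buf.getvalue()

    @classmethod
    def load(cls, ref_dir: str | Path) -> "ReferenceBundle":
        ref_dir = Path(ref_dir)
        genome = {r.id: str(r.seq) for r in SeqIO.parse(ref_dir / "genome.fa", "fasta")}
        loci = _loci_from_gff3((ref_dir / "mir.gff3").read_text(), genome)
        ncrnas = []
        for rec in SeqIO.parse(ref_dir / "ncrna.fa", "fasta"):
            cls_field = dict(
                kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
            ).get("class", "lincRNA")
            ncrnas.append(NcRNARecord(id=rec.id, rna_class=cls_field, seq=str(rec.seq)))
        return cls(genome=genome, loci=loci, ncrnas=ncrnas)


def _gff_line(chrom, ftype, start0, end0, strand, attrs) -> str:
    # 0-based half-open -> 1-based inclusive
    return (
        f"{chrom}\tmirkd\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
    )


def parse_gff3(text: str) -> pd.DataFrame:
    """Read a GFF3 body into a DataFrame (coordinates left 1-based inclusive)."""
    df = pd.read_csv(
        io.StringIO(text), sep="\t", comment="#", names=_GFF_COLUMNS, header=None,
        dtype={"start": int, "end": int},
    )
    df["attr"] = df["attributes"].map(
        lambda s: dict(kv.split("=", 1) for kv in s.rstrip(";").split(";"))
    )
    return df


def _loci_from_gff3(text: str, genome: dict[str, str]) -> list[MiRLocus]:
    df = parse_gff3(text)
    pri = df[df["type"] == "miRNA_primary_transcript"]
    mat = df[df["type"] == "miRNA"]
    loci = []
    for _, row in pri.iterrows():
        lid = row["attr"]["ID"]
        start, end = row["start"] - 1, row["end"]
        strand = row["strand"]
        seq = genome[row["seqid"]][start:end]
        if strand == "-":
            seq = revcomp(seq)
        arms: dict[str, tuple[int, int]] = {}
        for _, arow in mat[mat["attr"].map(lambda a: a.get("Derives_from")) == lid].iterrows():
            g0, g1 = arow["start"] - 1, arow["end"]
            if strand == "+":
                p0, p1 = g0 - start, g1 - start
            else:
                p0, p1 = end - g1, end - g0
            arm = "star" if arow["attr"]["Name"].endswith("*") else "mature"
            arms[arm] = (p0, p1)
        if "mature" not in arms:
            raise ValueError(f"locus {lid} has no mature feature")
        star = arms.get("star", (None, None))
        loci.append(MiRLocus(
            locus_id=lid, chrom=row["seqid"], start=start, end=end, strand=strand,
            precursor_seq=seq, mature_start=arms["mature"][0],
            mature_end=arms["mature"][1], star_start=star[0], star_end=star[1],
        ))
    return loci


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name.split()[0],
                   description=name[len(name.split()[0]):].strip())
         for name, seq in records),
        str(path), "fasta",
    )
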