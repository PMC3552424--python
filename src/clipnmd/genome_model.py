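"""Coordinate-resolved gene models and readers/writers for GFF3/FASTA/BED.

All internal coordinates are 0-based half-open on the forward genomic strand;
GFF3 (1-based closed) is converted at the I/O boundary, BED is native. Exons of
a gene are stored sorted 5'->3' along the transcript (i.e. by descending
genomic coordinate for minus-strand genes).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

EXON_KINDS = ("constitutive", "annotated-alternative", "cryptic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    id: str
    kind: str = "constitutive"

    def __post_init__(self) -> None:
        if self.kind not in EXON_KINDS:
            raise ValueError(f"unknown exon kind {self.kind!r}")


@dataclass
class GeneModel:
    """One merged transcript model per gene.

    ``exons`` hold every annotated exon (constitutive + annotated-alternative);
    cryptic exons may be grafted in later via :meth:`with_cryptic_exon`.
    ``cds_start``/``cds_end`` are transcript-relative offsets of the annotated
    start codon and the end of the canonical stop codon, measured on the
    canonical isoform (all annotated exons included).
    """

    gene_id: str
    strand: str
    exons: list[Exon]
    cds_start: int
    cds_end: int
    downstream_width: int = 10_000

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        if not (0 <= self.cds_start < self.cds_end):
            raise ValueError(f"{self.gene_id}: cds_start must precede cds_end")
        self.exons = sort_exons_transcript_order(self.exons, self.strand)
        ivs = [e.interval for e in self.exons]
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"{self.gene_id}: overlapping exons {a} / {b}")

    # ---- derived geometry -------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(e.interval.start for e in self.exons)
        end = max(e.interval.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def utr3(self) -> GenomicInterval | None:
        """Genomic interval of the 3'UTR part of the terminal exon."""
        parts = self._utr3_parts()
        return parts[-1] if parts else None

    @property
    def downstream_window(self) -> GenomicInterval:
        """Fixed-width window past the annotated 3' end, on the sense strand."""
        s = self.span
        if self.strand == "+":
            return GenomicInterval(self.chrom, s.end, s.end + self.downstream_width, "+")
        start = max(0, s.start - self.downstream_width)
        if start == s.start:  # gene abuts chromosome start
            raise ValueError(f"{self.gene_id}: no room for downstream window")
        return GenomicInterval(self.chrom, start, s.start, "-")

    def annotated_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.kind != "cryptic"]

    def alternative_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.kind == "annotated-alternative"]

    def exon_by_id(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise KeyError(f"{self.gene_id}: no exon {exon_id!r}")

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive annotated exons, in genomic coordinates."""
        ivs = sorted((e.interval for e in self.annotated_exons()), key=lambda i: i.start)
        out = []
        for a, b in zip(ivs, ivs[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def with_cryptic_exon(self, interval: GenomicInterval, exon_id: str) -> "GeneModel":
        """Return a copy of this model with one cryptic exon grafted in."""
        if interval.strand != self.strand or interval.chrom != self.chrom:
            raise ValueError(f"{self.gene_id}: cryptic exon on wrong chrom/strand")
        exons = list(self.exons) + [Exon(interval, exon_id, "cryptic")]
        return GeneModel(self.gene_id, self.strand, exons, self.cds_start,
                         self.cds_end, self.downstream_width)

    # ---- transcript/genomic coordinate maps -------------------------------

    def transcript_length(self, exon_ids: Iterable[str] | None = None) -> int:
        sel = self._select(exon_ids)
        return sum(e.interval.width for e in sel)

    def genomic_to_transcript(self, pos: int, exon_ids: Iterable[str] | None = None) -> int | None:
        """Map a genomic position onto the spliced transcript (None if intronic)."""
        off = 0
        for e in self._select(exon_ids):
            iv = e.interval
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return off + (pos - iv.start)
                return off + (iv.end - 1 - pos)
            off += iv.width
        return None

    def transcript_to_genomic(self, t: int, exon_ids: Iterable[str] | None = None) -> int:
        off = 0
        for e in self._select(exon_ids):
            iv = e.interval
            if t < off + iv.width:
                d = t - off
                return iv.start + d if self.strand == "+" else iv.end - 1 - d
            off += iv.width
        raise IndexError(f"{self.gene_id}: transcript offset {t} out of range")

    def _select(self, exon_ids: Iterable[str] | None) -> list[Exon]:
        if exon_ids is None:
            return [e for e in self.exons if e.kind != "cryptic"]
        wanted = set(exon_ids)
        missing = wanted - {e.id for e in self.exons}
        if missing:
            raise KeyError(f"{self.gene_id}: unknown exon id(s) {sorted(missing)}")
        return [e for e in self.exons if e.id in wanted]

    def _utr3_parts(self) -> list[GenomicInterval]:
        exons = self.annotated_exons()
        cum, parts = 0, []
        for e in exons:
            lo, hi = cum, cum + e.interval.width  # transcript-relative span
            if hi > self.cds_end:
                t0 = max(lo, self.cds_end)
                g0 = self.transcript_to_genomic(t0)
                g1 = self.transcript_to_genomic(hi - 1)
                a, b = (g0, g1 + 1) if self.strand == "+" else (g1, g0 + 1)
                parts.append(GenomicInterval(self.chrom, a, b, self.strand))
            cum = hi
        return parts

    def region_intervals(self) -> dict[str, list[GenomicInterval]]:
        """Genomic intervals of 5'UTR / CDS-exon / 3'UTR / intron for annotation."""
        out: dict[str, list[GenomicInterval]] = {
            "5utr": [], "cds": [], "3utr": [], "intron": self.introns()}
        cum = 0
        for e in self.annotated_exons():
            lo, hi = cum, cum + e.interval.width
            for label, t0, t1 in (("5utr", lo, min(hi, self.cds_start)),
                                  ("cds", max(lo, self.cds_start), min(hi, self.cds_end)),
                                  ("3utr", max(lo, self.cds_end), hi)):
                if t1 > t0:
                    g0 = self.transcript_to_genomic(t0)
                    g1 = self.transcript_to_genomic(t1 - 1)
                    a, b = (g0, g1 + 1) if self.strand == "+" else (g1, g0 + 1)
                    out[label].append(GenomicInterval(self.chrom, a, b, self.strand))
            cum = hi
        return out


@dataclass(frozen=True)
class Isoform:
    """An ordered exon combination of one gene (constitutive exons always in)."""

    gene_id: str
    included_exon_ids: tuple[str, ...]
    name: str = ""


def sort_exons_transcript_order(exons: Iterable[Exon], strand: str) -> list[Exon]:
    rev = strand == "-"
    return sorted(exons, key=lambda e: e.interval.start, reverse=rev)


class RepeatMask:
    """Strandless repeat intervals with O(log n) overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self.intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree and tree.overlaps_point(pos))

    def overlaps(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start, iv.end))

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "RepeatMask":
        mask = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                mask.add(GenomicInterval(f[0], int(f[1]), int(f[2]), "+"))
        return mask

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for iv in sorted(self.intervals):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Sequence store and spliced sequences
# ---------------------------------------------------------------------------

class SequenceStore:
    """In-memory genome: chromosome name -> forward-strand DNA string."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {k: str(v).upper() for k, v in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        """Strand-aware fetch (reverse-complemented for minus intervals)."""
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end "
                f"({len(seq)})")
        s = seq[iv.start:iv.end]
        return str(Seq(s).reverse_complement()) if iv.strand == "-" else s

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "SequenceStore":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._seqs):
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def spliced_sequence(gene: GeneModel, isoform: Isoform, genome: SequenceStore) -> str:
    """mRNA of an isoform: exon sequences concatenated in transcript order.

    Minus-strand genes are reverse-complemented per exon; total length equals
    the sum of the included exon widths.
    """
    exons = gene._select(isoform.included_exon_ids)
    return "".join(genome.fetch(e.interval) for e in exons)


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_gene_models(gff3_source: str | os.PathLike,
                     downstream_width: int = 10_000) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene -> mRNA -> exon/CDS hierarchy).

    Coordinates convert from 1-based closed to 0-based half-open. Exons are
    sorted 5'->3'. A feature missing its parent is a hard error naming the line.
    """
    text = _read_text(gff3_source)
    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    known = {f.id for f in db.all_features()}
    for feat in db.all_features(featuretype=("exon", "CDS", "mRNA")):
        for parent in feat.attributes.get("Parent", []):
            if parent not in known:
                raise ValueError(
                    f"{feat.featuretype} {feat.id!r} references missing parent "
                    f"{parent!r} (line: {feat})")
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                kind = ex.attributes.get("exon_kind", ["constitutive"])[0]
                eid = ex.attributes.get("Name", [ex.id])[0]
                exons.append(Exon(
                    GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand),
                    eid, kind))
        if not exons:
            raise ValueError(f"gene {gene.id!r} has no exon children")
        cds_start = int(gene.attributes["cds_start"][0])
        cds_end = int(gene.attributes["cds_end"][0])
        models.append(GeneModel(gene.id, gene.strand, exons, cds_start, cds_end,
                                downstream_width))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Deterministic GFF3 writer (1-based closed on disk); round-trips exactly."""
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.chrom, m.span.start, m.gene_id)):
        s = g.span
        attrs = f"ID={g.gene_id};cds_start={g.cds_start};cds_end={g.cds_end}"
        lines.append("\t".join([g.chrom, "clipnmd", "gene", str(s.start + 1),
                                str(s.end), ".", g.strand, ".", attrs]))
        mrna_id = f"{g.gene_id}.t1"
        lines.append("\t".join([g.chrom, "clipnmd", "mRNA", str(s.start + 1),
                                str(s.end), ".", g.strand, ".",
                                f"ID={mrna_id};Parent={g.gene_id}"]))
        for e in sorted(g.annotated_exons(), key=lambda e: e.interval.start):
            iv = e.interval
            lines.append("\t".join([
                g.chrom, "clipnmd", "exon", str(iv.start + 1), str(iv.end), ".",
                g.strand, ".",
                f"ID={g.gene_id}.{e.id};Name={e.id};Parent={mrna_id};exon_kind={e.kind}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_text(source: str | os.PathLike) -> str:
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            return fh.read()
    if isinstance(source, io.IOBase):
        return source.read()
    return str(source)
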