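"""CLIP-tag processing: alignment selection, duplicate collapse, cluster calling.

Clusters are called with a documented sweep-line merge of overlapping
same-strand tags (gap parameter ``g``, default 0 = book-ended tags merge, as in
``bedtools merge``). Each cluster carries biological complexity (BC, the number
of experiments in a compartment contributing >=1 tag), peak height (PH, the
maximum number of tags overlapping any single base) and a single region label
assigned at the peak summit.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_model import GeneModel, GenomicInterval, RepeatMask

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"
COMPARTMENTS = (NUCLEAR, CYTOPLASMIC)

REGION_LABELS = ("repeat", "3utr", "5utr", "cds", "intron", "downstream10k",
                 "intergenic")
# precedence when a summit hits several annotations (highest first)
_PRECEDENCE = {label: i for i, label in enumerate(REGION_LABELS)}

MIN_TAG_SIZE, MAX_TAG_SIZE = 25, 32


@dataclass(frozen=True)
class AlignmentCandidate:
    read_id: str
    locus: GenomicInterval
    mapped_size: int
    mismatches: int

    def __post_init__(self) -> None:
        if not (MIN_TAG_SIZE <= self.mapped_size <= MAX_TAG_SIZE):
            raise ValueError(f"mapped_size {self.mapped_size} outside 25-32")
        if not (0 <= self.mismatches <= 2):
            raise ValueError(f"mismatches {self.mismatches} outside 0-2")


@dataclass(frozen=True)
class ClipTag:
    interval: GenomicInterval
    experiment_id: str
    compartment: str
    read_id: str = ""

    @property
    def five_prime_start(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end


@dataclass
class ClipCluster:
    interval: GenomicInterval
    tags: list[ClipTag]
    region: str = "intergenic"
    gene_id: str | None = None

    @property
    def tag_count(self) -> int:
        return len(self.tags)

    def tag_count_in(self, compartment: str) -> int:
        return sum(1 for t in self.tags if t.compartment == compartment)

    def bc(self, compartment: str) -> int:
        return len({t.experiment_id for t in self.tags
                    if t.compartment == compartment})

    @property
    def bc_nuclear(self) -> int:
        return self.bc(NUCLEAR)

    @property
    def bc_cytoplasmic(self) -> int:
        return self.bc(CYTOPLASMIC)

    @property
    def peak_height(self) -> int:
        return self._peak()[0]

    @property
    def summit(self) -> int:
        """Leftmost genomic position reaching the peak height."""
        return self._peak()[1]

    def _peak(self) -> tuple[int, int]:
        events: list[tuple[int, int]] = []
        for t in self.tags:
            events.append((t.interval.start, 1))
            events.append((t.interval.end, -1))
        events.sort()
        depth = best = 0
        summit = self.tags[0].interval.start
        for pos, delta in events:
            depth += delta
            if depth > best:
                best, summit = depth, pos
        return best, summit


# ---------------------------------------------------------------------------
# Alignment selection
# ---------------------------------------------------------------------------

def select_alignment(candidates: Sequence[AlignmentCandidate]) -> AlignmentCandidate | None:
    """Pick the alignment for one read from its per-size candidate loci.

    A read is kept only if some mapped size yields a single (unambiguous)
    locus. Among unambiguous sizes, the largest whose mismatch count does not
    exceed that of the smallest unambiguous size wins; returns None otherwise.
    """
    by_size: dict[int, list[AlignmentCandidate]] = defaultdict(list)
    for c in candidates:
        by_size[c.mapped_size].append(c)
    unambiguous = {s: cs[0] for s, cs in by_size.items() if len(cs) == 1}
    if not unambiguous:
        return None
    smallest = min(unambiguous)
    budget = unambiguous[smallest].mismatches
    eligible = [s for s, c in unambiguous.items() if c.mismatches <= budget]
    return unambiguous[max(eligible)]


# ---------------------------------------------------------------------------
# Duplicate collapse
# ---------------------------------------------------------------------------

def collapse_duplicates(tags: Iterable[ClipTag]) -> list[ClipTag]:
    """Collapse tags sharing (chrom, strand, 5' start) within one experiment.

    The retained representative is the longest tag; ties break to the
    lexicographically smallest read id. Idempotent; never increases the count.
    """
    best: dict[tuple, ClipTag] = {}
    for t in tags:
        key = (t.interval.chrom, t.interval.strand, t.five_prime_start,
               t.experiment_id)
        cur = best.get(key)
        if (cur is None or t.interval.width > cur.interval.width
                or (t.interval.width == cur.interval.width
                    and t.read_id < cur.read_id)):
            best[key] = t
    return sorted(best.values(), key=_tag_key)


def _tag_key(t: ClipTag):
    iv = t.interval
    return (iv.chrom, iv.start, iv.end, iv.strand, t.experiment_id, t.read_id)


# ---------------------------------------------------------------------------
# Cluster calling (sweep line)
# ---------------------------------------------------------------------------

def call_clusters(tags: Iterable[ClipTag], min_tags: int = 2, gap: int = 0,
                  min_tags_scope: str = "combined") -> list[ClipCluster]:
    """Merge transitively overlapping same-strand tags into clusters.

    Tags whose intervals come within ``gap`` bases (gap=0: touching or
    overlapping) on the same chromosome and strand join one cluster; clusters
    with fewer than ``min_tags`` tags (combined across compartments by default,
    or within each separately with scope "per-compartment") are discarded.
    """
    if min_tags_scope not in ("combined", "per-compartment"):
        raise ValueError(f"unknown min_tags_scope {min_tags_scope!r}")
    groups: dict[tuple[str, str], list[ClipTag]] = defaultdict(list)
    for t in tags:
        groups[(t.interval.chrom, t.interval.strand)].append(t)
    clusters: list[ClipCluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda t: (t.interval.start, t.interval.end,
                                    t.experiment_id, t.read_id))
        bucket: list[ClipTag] = []
        right = None
        for t in members:
            if right is not None and t.interval.start > right + gap:
                clusters.append(_make_cluster(chrom, strand, bucket))
                bucket = []
                right = None
            bucket.append(t)
            right = max(right or 0, t.interval.end)
        if bucket:
            clusters.append(_make_cluster(chrom, strand, bucket))
    if min_tags_scope == "combined":
        clusters = [c for c in clusters if c.tag_count >= min_tags]
    else:
        clusters = [c for c in clusters
                    if max(c.tag_count_in(NUCLEAR),
                           c.tag_count_in(CYTOPLASMIC)) >= min_tags]
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                 c.interval.end, c.interval.strand))
    return clusters


def _make_cluster(chrom: str, strand: str, tags: list[ClipTag]) -> ClipCluster:
    start = min(t.interval.start for t in tags)
    end = max(t.interval.end for t in tags)
    return ClipCluster(GenomicInterval(chrom, start, end, strand), list(tags))


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

class RegionAnnotator:
    """Assigns one region label per cluster at its peak summit.

    Precedence when a summit hits several annotations:
    repeat > 3'UTR > 5'UTR > CDS-exon > intron > downstream10k > intergenic.
    Gene regions are matched strand-specifically; repeats are strandless.
    """

    def __init__(self, genes: Sequence[GeneModel],
                 repeat_mask: RepeatMask | None = None,
                 downstream_width: int = 10_000):
        from intervaltree import IntervalTree
        self.repeat_mask = repeat_mask
        self._trees: dict[tuple[str, str], "IntervalTree"] = defaultdict(IntervalTree)
        for g in genes:
            regions = g.region_intervals()
            for label, ivs in (("5utr", regions["5utr"]), ("cds", regions["cds"]),
                               ("3utr", regions["3utr"]),
                               ("intron", regions["intron"])):
                for iv in ivs:
                    self._trees[(g.chrom, g.strand)].addi(
                        iv.start, iv.end, (label, g.gene_id))
            try:
                g2 = GeneModel(g.gene_id, g.strand, list(g.annotated_exons()),
                               g.cds_start, g.cds_end, downstream_width)
                dw = g2.downstream_window
                self._trees[(g.chrom, g.strand)].addi(
                    dw.start, dw.end, ("downstream10k", g.gene_id))
            except ValueError:
                pass  # gene abuts chromosome start on minus strand

    def annotate_point(self, chrom: str, pos: int, strand: str) -> tuple[str, str | None]:
        if self.repeat_mask is not None and self.repeat_mask.overlaps_point(chrom, pos):
            return "repeat", None
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return "intergenic", None
        # deterministic tie-break: precedence first, then gene id
        hits = sorted((( _PRECEDENCE[iv.data[0]], iv.data[1] or "", iv.data)
                       for iv in tree.at(pos)))
        return hits[0][2] if hits else ("intergenic", None)

    def annotate(self, cluster: ClipCluster) -> ClipCluster:
        label, gid = self.annotate_point(cluster.interval.chrom, cluster.summit,
                                         cluster.interval.strand)
        cluster.region = label
        cluster.gene_id = gid
        return cluster

    def annotate_all(self, clusters: Iterable[ClipCluster]) -> list[ClipCluster]:
        return [self.annotate(c) for c in clusters]

    def annotate_tag(self, tag: ClipTag) -> tuple[str, str | None]:
        """Region of a single tag, judged at its leftmost position."""
        return self.annotate_point(tag.interval.chrom, tag.interval.start,
                                   tag.interval.strand)


def annotate_region(cluster: ClipCluster, genes: Sequence[GeneModel],
                    repeat_mask: RepeatMask | None = None,
                    downstream_width: int = 10_000) -> ClipCluster:
    return RegionAnnotator(genes, repeat_mask, downstream_width).annotate(cluster)


def region_distribution(clusters: Sequence[ClipCluster], bc_min: int = 0,
                        ph_min: int = 0, compartment: str | None = None,
                        weight_by_tags: bool = False) -> dict[str, float]:
    """Fraction of clusters (or tags) per region label over a BC/PH-filtered set.

    ``bc_min`` applies to the given compartment's BC (or the max across
    compartments if None). Raises if no cluster passes the filter.
    """
    kept = [c for c in clusters if _passes(c, bc_min, ph_min, compartment)]
    if not kept:
        raise ValueError("no clusters pass the BC/PH filter")
    weights: dict[str, float] = defaultdict(float)
    for c in kept:
        if not weight_by_tags:
            w = 1
        elif compartment:
            w = c.tag_count_in(compartment)
        else:
            w = c.tag_count
        weights[c.region] += w
    total = sum(weights.values())
    if total == 0:
        raise ValueError("no tags from the requested compartment in the "
                         "filtered clusters")
    return {r: weights[r] / total for r in sorted(weights)}


def _passes(c: ClipCluster, bc_min: int, ph_min: int,
            compartment: str | None) -> bool:
    bc = c.bc(compartment) if compartment else max(c.bc_nuclear, c.bc_cytoplasmic)
    return bc >= bc_min and c.peak_height >= ph_min


def tag_region_distribution(tags: Sequence[ClipTag],
                            annotator: RegionAnnotator) -> dict[str, float]:
    """Per-tag region fractions (each tag judged at its leftmost position)."""
    if not tags:
        raise ValueError("no tags")
    counts: dict[str, int] = defaultdict(int)
    for t in tags:
        counts[annotator.annotate_tag(t)[0]] += 1
    n = len(tags)
    return {r: counts[r] / n for r in sorted(counts)}


# ---------------------------------------------------------------------------
# BED I/O (tags: BED6+2 with name=experiment id, extra cols compartment, read id)
# ---------------------------------------------------------------------------

def read_tags_bed(path: str | os.PathLike) -> list[ClipTag]:
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            tags.append(ClipTag(
                GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                experiment_id=f[3], compartment=f[6],
                read_id=f[7] if len(f) > 7 else ""))
    return tags


def write_tags_bed(tags: Iterable[ClipTag], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in sorted(tags, key=_tag_key):
            iv = t.interval
            fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end),
                                t.experiment_id, "0", iv.strand,
                                t.compartment, t.read_id]) + "\n")


def write_clusters_bed(clusters: Iterable[ClipCluster],
                       path: str | os.PathLike) -> None:
    """BED6 + BC_nuc, BC_cyt, PH, region, gene_id columns."""
    with open(path, "w") as fh:
        for c in clusters:
            iv = c.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                f"cluster_{iv.chrom}_{iv.start}", str(c.tag_count), iv.strand,
                str(c.bc_nuclear), str(c.bc_cytoplasmic), str(c.peak_height),
                c.region, c.gene_id or "."]) + "\n")
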