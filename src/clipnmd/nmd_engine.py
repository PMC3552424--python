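"""Isoform construction, ORF/PTC detection, NMD classification and YCAY motifs.

The NMD call follows the field-standard 50-nt exon-junction-complex rule: a
transcript is an NMD target when its first in-frame stop codon is a premature
termination codon (PTC, i.e. upstream of the canonical stop) lying at least
``rule_distance`` nucleotides upstream of the final exon-exon junction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import GeneModel, Isoform, SequenceStore, spliced_sequence

STOP_CODONS = ("TAA", "TAG", "TGA")
_YCAY = re.compile(r"(?=([CT]CA[CT]))")


@dataclass(frozen=True)
class IsoformNmdCall:
    isoform: Isoform
    stop_position: int | None          # transcript offset of first in-frame stop
    last_junction_position: int | None  # transcript offset of final junction
    distance_stop_to_last_junction: int | None  # >0: stop upstream of junction
    is_ptc: bool
    is_nmd_target: bool
    nonstop: bool = False              # no in-frame stop before transcript end


@dataclass(frozen=True)
class YcayHit:
    position: int
    matched: str


@dataclass(frozen=True)
class YcayCluster:
    start: int
    end: int
    hit_count: int

    @property
    def density(self) -> float:
        """Hits per 100 nt of cluster extent."""
        return 100.0 * self.hit_count / (self.end - self.start)


# ---------------------------------------------------------------------------
# Isoform enumeration
# ---------------------------------------------------------------------------

def enumerate_isoforms(gene: GeneModel, alternative_exon_ids: Sequence[str],
                       combinations: str | Sequence[Sequence[str]] = "all",
                       ) -> list[Isoform]:
    """Isoforms as exon combinations; constitutive exons are always included.

    ``combinations="all"`` yields the 2^k subsets of the k alternative exons in
    deterministic order (subset size, then lexicographic); otherwise exactly
    the listed combinations.
    """
    exon_ids = {e.id for e in gene.exons}
    unknown = set(alternative_exon_ids) - exon_ids
    if unknown:
        raise KeyError(f"{gene.gene_id}: unknown alternative exon(s) {sorted(unknown)}")
    base = [e.id for e in gene.exons
            if e.kind == "constitutive" and e.id not in alternative_exon_ids]
    if combinations == "all":
        subsets: Iterable[tuple[str, ...]] = itertools.chain.from_iterable(
            itertools.combinations(sorted(alternative_exon_ids), k)
            for k in range(len(alternative_exon_ids) + 1))
    else:
        for combo in combinations:
            bad = set(combo) - set(alternative_exon_ids)
            if bad:
                raise KeyError(f"{gene.gene_id}: combination uses non-alternative "
                               f"exon(s) {sorted(bad)}")
        subsets = [tuple(c) for c in combinations]
    isoforms = []
    for subset in subsets:
        included = _transcript_order(gene, base + list(subset))
        name = "+".join(subset) if subset else "canonical"
        isoforms.append(Isoform(gene.gene_id, tuple(included), name))
    return isoforms


def _transcript_order(gene: GeneModel, exon_ids: Sequence[str]) -> list[str]:
    wanted = set(exon_ids)
    return [e.id for e in gene.exons if e.id in wanted]


# ---------------------------------------------------------------------------
# NMD classification
# ---------------------------------------------------------------------------

def classify_nmd(gene: GeneModel, isoform: Isoform, genome: SequenceStore,
                 rule_distance: int = 50) -> IsoformNmdCall:
    """Translate an isoform from the annotated start and apply the 50-nt rule.

    The start codon comes from annotation (genomic position mapped through
    shared exons); it must land on this isoform. The PTC test compares the
    first in-frame stop with the canonical stop mapped onto the isoform; when
    the canonical stop is absent (e.g. frameshift removed it), any in-frame
    stop before the final exon counts as a PTC.
    """
    mrna = spliced_sequence(gene, isoform, genome)
    exons = gene._select(isoform.included_exon_ids)
    widths = [e.interval.width for e in exons]

    start_genomic = gene.transcript_to_genomic(gene.cds_start)
    start = gene.genomic_to_transcript(start_genomic, isoform.included_exon_ids)
    if start is None:
        raise ValueError(f"{gene.gene_id}: annotated start codon not contained "
                         f"in isoform {isoform.name or isoform.included_exon_ids}")

    # first in-frame stop at/after the start codon
    stop = None
    for i in range(start, len(mrna) - 2, 3):
        if mrna[i:i + 3] in STOP_CODONS:
            stop = i
            break
    last_junction = sum(widths[:-1]) if len(widths) > 1 else None
    if stop is None:
        return IsoformNmdCall(isoform, None, last_junction, None,
                              is_ptc=False, is_nmd_target=False, nonstop=True)

    canonical_stop_genomic = gene.transcript_to_genomic(gene.cds_end - 1)
    canon = gene.genomic_to_transcript(canonical_stop_genomic,
                                       isoform.included_exon_ids)
    if canon is not None:
        canonical_stop_start = canon - 2  # offset of the stop codon's first base
        is_ptc = stop < canonical_stop_start
    else:
        is_ptc = last_junction is not None and stop + 3 <= last_junction
    distance = None if last_junction is None else last_junction - (stop + 3)
    is_nmd = bool(is_ptc and distance is not None and distance >= rule_distance)
    return IsoformNmdCall(isoform, stop, last_junction, distance, is_ptc, is_nmd)


def translate_first_orf_oracle(mrna: str, start: int) -> int | None:
    """Independent codon-by-codon scan for the first in-frame stop (test oracle)."""
    i = start
    while i + 3 <= len(mrna):
        if mrna[i:i + 3] in STOP_CODONS:
            return i
        i += 3
    return None


# ---------------------------------------------------------------------------
# YCAY scanning, clustering, mutagenesis
# ---------------------------------------------------------------------------

def scan_ycay(sequence: str) -> list[YcayHit]:
    """All (possibly overlapping) YCAY = [CT]CA[CT] matches, left to right."""
    seq = sequence.upper()
    return [YcayHit(m.start(), m.group(1)) for m in _YCAY.finditer(seq)]


def ycay_clusters(hits: Sequence[YcayHit], window: int = 100,
                  min_hits: int = 3) -> list[YcayCluster]:
    """Merge qualifying hit windows into clusters.

    A window anchored at a hit spans [pos, pos + window) over hit start
    positions; anchored windows holding >= ``min_hits`` hits qualify, and
    qualifying windows sharing hits merge greedily left to right. Cluster
    extent runs from its first hit to the end of its last matched tetramer.
    """
    pos = [h.position for h in hits]
    if sorted(pos) != pos:
        raise ValueError("hits must be sorted by position")
    n = len(pos)
    qualifying: list[tuple[int, int]] = []  # index ranges [i, j] inclusive
    for i in range(n):
        j = i
        while j + 1 < n and pos[j + 1] < pos[i] + window:
            j += 1
        if j - i + 1 >= min_hits:
            qualifying.append((i, j))
    clusters: list[YcayCluster] = []
    cur: tuple[int, int] | None = None
    for i, j in qualifying:
        if cur is not None and i <= cur[1]:
            cur = (cur[0], max(cur[1], j))
        else:
            if cur is not None:
                clusters.append(_ycay_cluster(pos, cur))
            cur = (i, j)
    if cur is not None:
        clusters.append(_ycay_cluster(pos, cur))
    return clusters


def _ycay_cluster(pos: Sequence[int], rng: tuple[int, int]) -> YcayCluster:
    i, j = rng
    return YcayCluster(pos[i], pos[j] + 4, j - i + 1)


def mutate_ycay_to_yaay(sequence: str) -> str:
    """Disrupt every YCAY site by iterated leftmost C->A replacement.

    Repeatedly rescans because a replacement can expose a new overlapping
    match; terminates with zero YCAY hits and unchanged length.
    """
    seq = list(sequence.upper())
    while True:
        hits = scan_ycay("".join(seq))
        if not hits:
            return "".join(seq)
        seq[hits[0].position + 1] = "A"
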