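"""Nuclear-vs-cytoplasmic binding comparison.

Per-gene tag totals over BC-filtered clusters, their squared Pearson
correlation (computed on a log2(count+1) scale by default, since per-gene tag
totals are heavy-tailed), overlap categories of robust cytoplasmic clusters
against the nuclear map, and per-gene intron/3'UTR tag-fraction profiles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .clip_processing import CYTOPLASMIC, NUCLEAR, ClipCluster

SHARED_ROBUST = "shared-robust"
WEAKER_NUCLEAR = "weaker-nuclear"
CYTOPLASM_UNIQUE = "cytoplasm-unique"
NO_NUCLEAR_GENE = "no-nuclear-gene"


@dataclass(frozen=True)
class GeneTagTotals:
    gene_id: str
    total_tags_nuclear: int
    total_tags_cytoplasmic: int


@dataclass(frozen=True)
class OverlapCategory:
    cluster: ClipCluster
    gene_id: str | None
    category: str


@dataclass(frozen=True)
class TagFractionProfile:
    gene_id: str
    fraction_intronic: float
    fraction_3utr: float
    total_tags: int


def per_gene_totals(clusters: Sequence[ClipCluster],
                    bc_min: int = 4) -> list[GeneTagTotals]:
    """Sum cluster tags gene-by-gene per compartment over BC-passing clusters.

    A cluster contributes its nuclear tags when its nuclear BC passes, and its
    cytoplasmic tags when its cytoplasmic BC passes; intergenic clusters are
    excluded.
    """
    nuc: dict[str, int] = defaultdict(int)
    cyt: dict[str, int] = defaultdict(int)
    genes = set()
    for c in clusters:
        if c.gene_id is None:
            continue
        genes.add(c.gene_id)
        if c.bc(NUCLEAR) >= bc_min:
            nuc[c.gene_id] += c.tag_count_in(NUCLEAR)
        if c.bc(CYTOPLASMIC) >= bc_min:
            cyt[c.gene_id] += c.tag_count_in(CYTOPLASMIC)
    return [GeneTagTotals(g, nuc[g], cyt[g]) for g in sorted(genes)]


def compartment_r2(totals: Sequence[GeneTagTotals],
                   scale: str = "log2") -> float:
    """Coefficient of determination of per-gene nuclear vs cytoplasmic totals."""
    if len(totals) < 3:
        raise ValueError("need >=3 genes for a correlation")
    x = np.array([t.total_tags_nuclear for t in totals], dtype=float)
    y = np.array([t.total_tags_cytoplasmic for t in totals], dtype=float)
    if scale == "log2":
        x, y = np.log2(x + 1), np.log2(y + 1)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one compartment's totals")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def overlap_categories(cyt_clusters: Sequence[ClipCluster],
                       nuc_clusters: Sequence[ClipCluster],
                       bc_min: int = 4, ph_min: int = 11,
                       weaker_scope: str = "overlapping",
                       ) -> list[OverlapCategory]:
    """Categorize each robust cytoplasmic cluster against the nuclear map.

    shared-robust: an overlapping nuclear cluster also passes the robust
    filter; weaker-nuclear: some nuclear cluster overlaps (or, with
    ``weaker_scope="gene"``, the gene has any nuclear cluster); cytoplasm-unique:
    no overlapping nuclear cluster but the gene has nuclear clusters elsewhere;
    no-nuclear-gene: the gene has no nuclear clusters at all.
    """
    if weaker_scope not in ("overlapping", "gene"):
        raise ValueError(f"unknown weaker_scope {weaker_scope!r}")
    robust = [c for c in cyt_clusters
              if c.bc(CYTOPLASMIC) >= bc_min and c.peak_height >= ph_min]
    nuc_by_gene: dict[str | None, list[ClipCluster]] = defaultdict(list)
    for n in nuc_clusters:
        nuc_by_gene[n.gene_id].append(n)
    out = []
    for c in robust:
        overlapping = [n for n in nuc_clusters
                       if n.interval.overlaps(c.interval)]
        gene_nuc = nuc_by_gene.get(c.gene_id, []) if c.gene_id else []
        if any(n.bc(NUCLEAR) >= bc_min and n.peak_height >= ph_min
               for n in overlapping):
            cat = SHARED_ROBUST
        elif overlapping or (weaker_scope == "gene" and gene_nuc):
            cat = WEAKER_NUCLEAR
        elif gene_nuc:
            cat = CYTOPLASM_UNIQUE
        else:
            cat = NO_NUCLEAR_GENE
        out.append(OverlapCategory(c, c.gene_id, cat))
    return out


def category_counts(categories: Sequence[OverlapCategory]) -> dict[str, int]:
    counts = {SHARED_ROBUST: 0, WEAKER_NUCLEAR: 0, CYTOPLASM_UNIQUE: 0,
              NO_NUCLEAR_GENE: 0}
    for c in categories:
        counts[c.category] += 1
    return counts


def tag_fraction_profiles(clusters: Sequence[ClipCluster],
                          min_total: int = 5) -> list[TagFractionProfile]:
    """Per-gene intronic / 3'UTR tag fractions, for genes with > min_total tags."""
    per_gene: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for c in clusters:
        if c.gene_id is None:
            continue
        per_gene[c.gene_id][c.region] += c.tag_count
    profiles = []
    for gene_id in sorted(per_gene):
        counts = per_gene[gene_id]
        total = sum(counts.values())
        if total <= min_total:
            continue
        profiles.append(TagFractionProfile(
            gene_id, counts.get("intron", 0) / total,
            counts.get("3utr", 0) / total, total))
    return profiles
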