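"""Tag processing: alignment selection, dedup, sweep-line clusters, regions.

Each non-trivial operation is checked against an independent brute-force
oracle implemented here from the definitions alone.
"""

import itertools

import numpy as np
import pytest

from clipnmd.clip_processing import (AlignmentCandidate, ClipCluster, ClipTag,
                                     RegionAnnotator, call_clusters,
                                     collapse_duplicates, region_distribution,
                                     select_alignment)
from clipnmd.genome_model import (Exon, GeneModel, GenomicInterval, RepeatMask)


def tag(start, end, strand="+", exp="nuc1", comp="nuclear", rid="r0",
        chrom="chr1"):
    return ClipTag(GenomicInterval(chrom, start, end, strand), exp, comp, rid)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def select_alignment_oracle(candidates):
    """Direct enumeration of the mapping-selection rule: per-size uniqueness,
    then the largest unambiguous size whose mismatches do not exceed those of
    the smallest unambiguous size."""
    sizes = sorted({c.mapped_size for c in candidates})
    unique = {}
    for s in sizes:
        at_s = [c for c in candidates if c.mapped_size == s]
        if len(at_s) == 1:
            unique[s] = at_s[0]
    if not unique:
        return None
    smallest = min(unique)
    best = unique[smallest]
    for s in sorted(unique):
        if unique[s].mismatches <= unique[smallest].mismatches:
            best = unique[s]
    return best


def clusters_oracle(tags):
    """O(n^2) transitive-overlap grouping (gap 0 = touching merges)."""
    tags = list(tags)
    parent = list(range(len(tags)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(tags)), 2):
        a, b = tags[i].interval, tags[j].interval
        if (a.chrom, a.strand) == (b.chrom, b.strand) \
                and a.start <= b.end and b.start <= a.end:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(tags)):
        groups.setdefault(find(i), []).append(tags[i])
    return sorted((min(t.interval.start for t in g),
                   max(t.interval.end for t in g),
                   g[0].interval.chrom, g[0].interval.strand, len(g))
                  for g in groups.values())


def peak_height_oracle(tags):
    """Naive per-base coverage counter."""
    lo = min(t.interval.start for t in tags)
    hi = max(t.interval.end for t in tags)
    cov = np.zeros(hi - lo, dtype=int)
    for t in tags:
        cov[t.interval.start - lo:t.interval.end - lo] += 1
    return int(cov.max())


def random_tags(rng, n, span=300, chrom_choices=("chr1",), both_strands=True):
    tags = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 40))
        strand = "+-"[int(rng.integers(0, 2))] if both_strands else "+"
        exp = f"nuc{int(rng.integers(1, 5))}"
        tags.append(tag(start, start + length, strand, exp, "nuclear",
                        f"r{i:04d}", chrom_choices[int(rng.integers(0, len(chrom_choices)))]))
    return tags


# ---------------------------------------------------------------------------
# alignment selection
# ---------------------------------------------------------------------------

class TestSelectAlignment:
    def A(self, locus, size, mm, rid="r"):
        return AlignmentCandidate(rid, GenomicInterval("chr1", locus,
                                                       locus + size, "+"),
                                  size, mm)

    def test_single_unambiguous(self):
        c = self.A(1000, 28, 0)
        assert select_alignment([c]) is c

    def test_ambiguous_small_unique_large(self):
        """Ambiguous at 25; the smallest unambiguous size is 32 itself."""
        cands = [self.A(1000, 25, 0), self.A(9000, 25, 0), self.A(1000, 32, 1)]
        assert select_alignment(cands).mapped_size == 32

    def test_larger_size_rejected_when_mismatches_increase(self):
        cands = [self.A(1000, 28, 0), self.A(1000, 32, 2)]
        got = select_alignment(cands)
        assert (got.mapped_size, got.mismatches) == (28, 0)

    def test_larger_size_taken_when_mismatches_do_not_increase(self):
        cands = [self.A(1000, 28, 1), self.A(1000, 31, 1)]
        assert select_alignment(cands).mapped_size == 31

    def test_no_unambiguous_size_returns_none(self):
        cands = [self.A(1000, 28, 0), self.A(5000, 28, 0)]
        assert select_alignment(cands) is None

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(400):
            n = int(rng.integers(1, 7))
            cands = [self.A(int(rng.integers(0, 4)) * 1000,
                            int(rng.integers(25, 33)),
                            int(rng.integers(0, 3)), f"c{i}")
                     for i, n_ in zip(range(n), range(n))]
            got = select_alignment(cands)
            want = select_alignment_oracle(cands)
            assert (got is None) == (want is None)
            if got is not None:
                assert (got.mapped_size, got.mismatches,
                        got.locus) == (want.mapped_size, want.mismatches,
                                       want.locus)


# ---------------------------------------------------------------------------
# duplicate collapse
# ---------------------------------------------------------------------------

class TestCollapseDuplicates:
    def test_keeps_longest_at_shared_start(self):
        tags = [tag(100, 128, rid="a"), tag(100, 130, rid="b"),
                tag(100, 132, rid="c")]
        out = collapse_duplicates(tags)
        assert len(out) == 1 and out[0].interval.end == 132

    def test_length_tie_breaks_to_first_read_id(self):
        tags = [tag(100, 130, rid="zz"), tag(100, 130, rid="aa")]
        assert collapse_duplicates(tags)[0].read_id == "aa"

    def test_opposite_strands_both_kept(self):
        tags = [tag(100, 130, "+"), tag(100, 130, "-")]
        # note: 5' start of the minus tag is its end coordinate
        assert len(collapse_duplicates(tags)) == 2

    def test_minus_strand_key_uses_five_prime_end(self):
        tags = [tag(100, 130, "-", rid="a"), tag(90, 130, "-", rid="b")]
        out = collapse_duplicates(tags)
        assert len(out) == 1 and out[0].interval.width == 40

    def test_experiments_collapse_independently(self):
        tags = [tag(100, 130, exp="nuc1"), tag(100, 130, exp="nuc2")]
        assert len(collapse_duplicates(tags)) == 2

    def test_count_matches_distinct_key_oracle(self, rng):
        tags = random_tags(rng, 10_000, span=2000)
        keys = {(t.interval.chrom, t.interval.strand, t.five_prime_start,
                 t.experiment_id) for t in tags}
        assert len(collapse_duplicates(tags)) == len(keys)

    def test_idempotent_and_never_grows(self, rng):
        tags = random_tags(rng, 500, span=150)
        once = collapse_duplicates(tags)
        assert len(once) <= len(tags)
        assert collapse_duplicates(once) == once


# ---------------------------------------------------------------------------
# cluster calling
# ---------------------------------------------------------------------------

class TestCallClusters:
    def test_single_tag_filtered_by_min_tags(self):
        assert call_clusters([tag(0, 30)]) == []

    def test_chain_of_three_with_peak_height(self):
        tags = [tag(0, 30, rid="a"), tag(10, 40, rid="b"), tag(20, 50, rid="c")]
        (c,) = call_clusters(tags)
        assert (c.interval.start, c.interval.end) == (0, 50)
        assert c.peak_height == 3

    def test_bc_counts_experiments_per_compartment(self):
        tags = [tag(0, 30, exp=e, comp="nuclear", rid=e)
                for e in ("nuc1", "nuc2", "nuc4")]
        tags.append(tag(5, 35, exp="cyt2", comp="cytoplasmic", rid="c"))
        (c,) = call_clusters(tags)
        assert (c.bc_nuclear, c.bc_cytoplasmic) == (3, 1)

    def test_antisense_overlap_does_not_merge(self):
        tags = [tag(0, 30, "+", rid="a"), tag(10, 40, "+", rid="b"),
                tag(0, 30, "-", rid="c"), tag(10, 40, "-", rid="d")]
        out = call_clusters(tags)
        assert len(out) == 2
        assert {c.interval.strand for c in out} == {"+", "-"}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            tags = random_tags(rng, int(rng.integers(2, 120)),
                               span=int(rng.integers(100, 600)))
            got = call_clusters(tags, min_tags=1)
            want = clusters_oracle(tags)
            assert sorted((c.interval.start, c.interval.end, c.interval.chrom,
                           c.interval.strand, c.tag_count)
                          for c in got) == want

    def test_peak_height_matches_naive_coverage(self, rng):
        for _ in range(60):
            tags = random_tags(rng, int(rng.integers(2, 80)), span=200,
                               both_strands=False)
            for c in call_clusters(tags, min_tags=1):
                assert c.peak_height == peak_height_oracle(c.tags)

    def test_invariant_to_tag_order(self, rng):
        tags = random_tags(rng, 80, span=400)
        a = call_clusters(tags)
        perm = [tags[i] for i in rng.permutation(len(tags))]
        b = call_clusters(perm)
        assert [(c.interval, c.tag_count, c.peak_height) for c in a] == \
               [(c.interval, c.tag_count, c.peak_height) for c in b]

    def test_min_tags_monotonicity(self, rng):
        tags = random_tags(rng, 200, span=800)
        sizes = [len(call_clusters(tags, min_tags=k)) for k in (1, 2, 3, 5)]
        assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

def _annotation_genes():
    # gene A (+): exons [1000,1200) and [2000,2400); CDS covers [100, 500)
    # of the 600 nt transcript -> 100 nt 5'UTR, 100 nt 3'UTR
    ga = GeneModel("gA", "+",
                   [Exon(GenomicInterval("chr1", 1000, 1200, "+"), "e1"),
                    Exon(GenomicInterval("chr1", 2000, 2400, "+"), "e2")],
                   cds_start=100, cds_end=500, downstream_width=1000)
    # gene B (+): single exon overlapping gene A's 3'UTR region, so points in
    # [2300,2400) are both A-3'UTR and B-intron-free CDS... use an intron:
    gb = GeneModel("gB", "+",
                   [Exon(GenomicInterval("chr1", 2200, 2250, "+"), "e1"),
                    Exon(GenomicInterval("chr1", 2600, 2700, "+"), "e2")],
                   cds_start=10, cds_end=120, downstream_width=1000)
    return ga, gb


class TestRegionAnnotation:
    def test_intron_summit(self):
        ga, gb = _annotation_genes()
        ann = RegionAnnotator([ga, gb])
        assert ann.annotate_point("chr1", 1500, "+") == ("intron", "gA")

    def test_precedence_3utr_over_intron_of_overlapping_gene(self):
        """Position 2350: 3'UTR of gene A and intron of gene B -> 3'UTR."""
        ga, gb = _annotation_genes()
        # exhaustive overlap listing oracle
        hits = set()
        for g in (ga, gb):
            for label, ivs in g.region_intervals().items():
                for iv in ivs:
                    if iv.contains_point("chr1", 2350):
                        hits.add((label, g.gene_id))
        assert hits == {("3utr", "gA"), ("intron", "gB")}
        ann = RegionAnnotator([ga, gb])
        assert ann.annotate_point("chr1", 2350, "+") == ("3utr", "gA")

    def test_downstream_window(self):
        ga, gb = _annotation_genes()
        ann = RegionAnnotator([ga], downstream_width=10_000)
        assert ann.annotate_point("chr1", 2400 + 5000, "+") == \
            ("downstream10k", "gA")
        assert ann.annotate_point("chr1", 2400 + 10_001, "+")[0] == "intergenic"

    def test_repeat_overrides_everything(self):
        ga, gb = _annotation_genes()
        mask = RepeatMask([GenomicInterval("chr1", 1400, 1600, "+")])
        ann = RegionAnnotator([ga, gb], repeat_mask=mask)
        assert ann.annotate_point("chr1", 1500, "+") == ("repeat", None)

    def test_cluster_annotated_at_summit(self):
        ga, gb = _annotation_genes()
        # two tags overlap inside the intron, one reaches into the exon
        tags = [tag(1950, 1990, rid="a"), tag(1955, 1995, rid="b"),
                tag(1990, 2020, rid="c")]
        (c,) = call_clusters(tags)
        RegionAnnotator([ga]).annotate(c)
        assert (c.region, c.gene_id) == ("intron", "gA")


class TestRegionDistribution:
    def _clusters(self, regions):
        out = []
        for i, r in enumerate(regions):
            c = ClipCluster(GenomicInterval("chr1", i * 100, i * 100 + 50, "+"),
                            [tag(i * 100, i * 100 + 50, rid=f"r{i}")])
            c.region = r
            out.append(c)
        return out

    def test_all_intronic(self):
        dist = region_distribution(self._clusters(["intron"] * 4))
        assert dist == {"intron": 1.0}

    def test_fractions_sum_to_one(self):
        dist = region_distribution(
            self._clusters(["intron", "intron", "3utr", "cds"]))
        assert dist["intron"] == pytest.approx(0.5)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_bc_filter_semantics(self):
        clusters = []
        for bc in (1, 2, 3, 4):
            tags = [tag(0, 30, exp=f"nuc{i}", rid=f"{bc}{i}")
                    for i in range(1, bc + 1)]
            (c,) = call_clusters(tags, min_tags=1)
            c.region = "intron"
            clusters.append(c)
        # only the BC=4 cluster survives bc_min=4
        dist = region_distribution(clusters, bc_min=4)
        assert dist == {"intron": 1.0}
        with pytest.raises(ValueError, match="no clusters pass"):
            region_distribution(clusters, bc_min=5)
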