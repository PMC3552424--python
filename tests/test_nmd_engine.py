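"""Isoform enumeration, PTC/NMD classification and YCAY motif utilities."""

import re

import pytest

from clipnmd.genome_model import (Exon, GeneModel, GenomicInterval, Isoform,
                                  SequenceStore, spliced_sequence)
from clipnmd.nmd_engine import (classify_nmd, enumerate_isoforms,
                                mutate_ycay_to_yaay, scan_ycay,
                                translate_first_orf_oracle, ycay_clusters)
from clipnmd.synthetic_data import generate_genome
from conftest import small_config

STOPS = ("TAA", "TAG", "TGA")


def build_gene(exon_seqs, cds_start, cds_end, intron=100, chrom="c",
               kinds=None):
    """Lay exon sequences on a plus-strand chromosome with fixed introns."""
    seq_parts, exons, pos = [], [], 0
    for i, es in enumerate(exon_seqs):
        kind = kinds[i] if kinds else "constitutive"
        exons.append(Exon(GenomicInterval(chrom, pos, pos + len(es), "+"),
                          f"e{i}", kind))
        seq_parts.append(es)
        seq_parts.append("G" * intron)
        pos += len(es) + intron
    genome = SequenceStore({chrom: "".join(seq_parts)})
    gene = GeneModel("g", "+", exons, cds_start, cds_end)
    return gene, genome


class TestEnumerateIsoforms:
    def test_no_alternatives_gives_canonical_only(self, small_dataset):
        g = small_dataset.genes[0]
        isos = enumerate_isoforms(g, [])
        assert len(isos) == 1 and isos[0].name == "canonical"

    def test_three_alternatives_give_eight(self):
        gene, _ = build_gene(["ATGAAA", "AAA", "BBB".replace("B", "C"),
                              "CCC", "TAAGGG"], 0, 18,
                             kinds=["constitutive", "annotated-alternative",
                                    "annotated-alternative",
                                    "annotated-alternative", "constitutive"])
        isos = enumerate_isoforms(gene, ["e1", "e2", "e3"])
        assert len(isos) == 8
        # constitutive exons present in every isoform
        assert all({"e0", "e4"} <= set(i.included_exon_ids) for i in isos)

    def test_explicit_combination_list(self):
        gene, _ = build_gene(["ATG", "AAA", "CCC", "GGG", "TAA"], 0, 15)
        combos = [("e1",), ("e1", "e2"), ("e3",), ("e1", "e2", "e3")]
        isos = enumerate_isoforms(gene, ["e1", "e2", "e3"], combos)
        assert len(isos) == 4
        assert isos[2].included_exon_ids == ("e0", "e3", "e4")

    def test_unknown_exon_id_raises(self, small_dataset):
        with pytest.raises(KeyError):
            enumerate_isoforms(small_dataset.genes[0], ["nope"])


class TestClassifyNmd:
    def test_canonical_isoforms_are_never_nmd(self, small_dataset):
        ds = small_dataset
        for g in ds.genes:
            iso = Isoform(g.gene_id, tuple(e.id for e in g.annotated_exons()))
            call = classify_nmd(g, iso, ds.genome)
            assert not call.is_ptc and not call.is_nmd_target

    def test_planted_cryptic_inclusions_are_all_nmd(self, small_dataset):
        """Every planted frameshifting exon makes its isoform an NMD target."""
        ds = small_dataset
        gene_by_id = {g.gene_id: g for g in ds.genes}
        assert ds.truth.events
        for ev in ds.truth.events:
            aug = gene_by_id[ev.gene_id].with_cryptic_exon(
                ev.cryptic_exon, ev.cryptic_exon_id)
            iso = Isoform(aug.gene_id, tuple(e.id for e in aug.exons))
            call = classify_nmd(aug, iso, ds.genome)
            assert call.is_ptc and call.is_nmd_target

    def test_agrees_with_codon_scan_oracle_on_random_isoforms(self, rng):
        """Random exon subsets of random genes: first-stop position matches an
        independent codon-by-codon translator."""
        ds = generate_genome(small_config(n_genes=8), seed=11)
        checked = 0
        for _ in range(150):
            g = ds.genes[int(rng.integers(0, len(ds.genes)))]
            const = [e.id for e in g.exons if e.kind == "constitutive"]
            optional = [e.id for e in g.exons if e.kind != "constitutive"]
            keep = const + [x for x in optional if rng.random() < 0.5]
            # also drop a random internal constitutive exon half the time to
            # create frameshift-free deletions (codon-aligned junctions)
            if len(const) > 3 and rng.random() < 0.5:
                keep.remove(const[int(rng.integers(1, len(const) - 1))])
            iso = Isoform(g.gene_id,
                          tuple(e.id for e in g.exons if e.id in set(keep)))
            if g.genomic_to_transcript(
                    g.transcript_to_genomic(g.cds_start),
                    iso.included_exon_ids) is None:
                continue
            call = classify_nmd(g, iso, ds.genome)
            mrna = spliced_sequence(g, iso, ds.genome)
            start = g.genomic_to_transcript(
                g.transcript_to_genomic(g.cds_start), iso.included_exon_ids)
            want = translate_first_orf_oracle(mrna, start)
            assert call.stop_position == want
            checked += 1
        assert checked > 100

    def test_ptc_within_rule_distance_is_not_nmd(self):
        """PTC 20 nt upstream of the last junction: PTC yes, NMD no."""
        # e0: ATG + 9 codons; stop lands in e1, 20 nt before the junction
        e0 = "ATG" + "GGC" * 9
        e1 = "GGA" * 4 + "TAA" + "GCC" * 5 + "GC"  # stop at e1 offset 12, len 32
        e2 = "GGG" * 20 + "TGA" + "AAAA"
        cds_end = len(e0) + len(e1) + len(e2) - 4
        gene, genome = build_gene([e0, e1, e2], 0, cds_end)
        iso = Isoform("g", ("e0", "e1", "e2"))
        call = classify_nmd(gene, iso, genome)
        assert call.is_ptc
        assert call.distance_stop_to_last_junction == len(e1) - 12 - 3
        assert call.distance_stop_to_last_junction < 50
        assert not call.is_nmd_target

    def test_distant_ptc_is_nmd(self):
        e0 = "ATG" + "GGC" * 5 + "TAA" + "GGC" * 30
        e1 = "GGA" * 40
        e2 = "GGG" * 20 + "TGA" + "AAAA"
        cds_end = len(e0) + len(e1) + len(e2) - 4
        gene, genome = build_gene([e0, e1, e2], 0, cds_end)
        call = classify_nmd(gene, Isoform("g", ("e0", "e1", "e2")), genome)
        assert call.is_ptc and call.is_nmd_target

    def test_no_stop_flags_nonstop_not_nmd(self):
        gene, genome = build_gene(["ATG" + "GGC" * 10, "GCA" * 10], 0, 63)
        call = classify_nmd(gene, Isoform("g", ("e0", "e1")), genome)
        assert call.nonstop and not call.is_nmd_target and not call.is_ptc

    def test_frame_preserving_stop_free_exon_never_flips_ptc(self, rng):
        """Skipping/including a length-0-mod-3, stop-free alternative exon
        leaves is_ptc unchanged."""
        ds = generate_genome(small_config(n_genes=10, alt_exon_prob=1.0),
                             seed=3)
        tested = 0
        for g in ds.genes:
            alts = g.alternative_exons()
            if not alts:
                continue
            with_alt = Isoform(g.gene_id,
                               tuple(e.id for e in g.annotated_exons()))
            without = Isoform(g.gene_id,
                              tuple(e.id for e in g.annotated_exons()
                                    if e.id != alts[0].id))
            a = classify_nmd(g, with_alt, ds.genome)
            b = classify_nmd(g, without, ds.genome)
            assert a.is_ptc == b.is_ptc
            tested += 1
        assert tested >= 3

    def test_rule_distance_monotonicity(self, small_dataset):
        """Raising the junction-distance threshold never creates NMD calls."""
        ds = small_dataset
        gene_by_id = {g.gene_id: g for g in ds.genes}
        for ev in ds.truth.events:
            aug = gene_by_id[ev.gene_id].with_cryptic_exon(
                ev.cryptic_exon, ev.cryptic_exon_id)
            iso = Isoform(aug.gene_id, tuple(e.id for e in aug.exons))
            calls = [classify_nmd(aug, iso, ds.genome, rule_distance=d)
                     .is_nmd_target for d in (0, 50, 10_000)]
            assert all(b <= a for a, b in zip(calls, calls[1:]))


class TestYcay:
    def test_hand_scanned_examples(self):
        assert [h.position for h in scan_ycay("TCATTCATT")] == [0, 4]
        assert scan_ycay("GGGG") == []
        # overlapping matches allowed
        assert [h.position for h in scan_ycay("TCATCAT")] == [0, 3]

    def test_matches_brute_force_regex_free_scan(self, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(4, 60))))
            want = [i for i in range(len(seq) - 3)
                    if seq[i] in "CT" and seq[i + 1] == "C"
                    and seq[i + 2] == "A" and seq[i + 3] in "CT"]
            assert [h.position for h in scan_ycay(seq)] == want

    def test_cluster_basic_cases(self):
        hits = scan_ycay("TCAT" * 3 + "G" * 200)   # 3+ hits within 12 nt
        assert len(ycay_clusters(hits)) == 1
        assert ycay_clusters(scan_ycay("TCATGGGGTCAT")) == []  # only 2 hits

    def test_clusters_match_all_windows_oracle(self, rng):
        """Anchored-window definition re-derived by brute force enumeration."""
        for _ in range(200):
            pos = sorted(set(int(p) for p in
                             rng.integers(0, 400, size=int(rng.integers(0, 50)))))
            hits = [type("H", (), {"position": p})() for p in pos]
            window, min_hits = 100, 3
            qual = []
            for i, p in enumerate(pos):
                members = [j for j, q in enumerate(pos) if p <= q < p + window]
                if len(members) >= min_hits:
                    qual.append(set(members))
            merged = []
            for s in qual:
                if merged and merged[-1] & s:
                    merged[-1] |= s
                else:
                    merged.append(set(s))
            want = [(pos[min(s)], pos[max(s)] + 4, len(s)) for s in merged]
            got = [(c.start, c.end, c.hit_count)
                   for c in ycay_clusters(hits, window, min_hits)]
            assert got == want

    def test_mutagenesis_examples_and_fixed_point(self):
        assert mutate_ycay_to_yaay("TCAT") == "TAAT"
        assert mutate_ycay_to_yaay("TCATCAT") == "TAATAAT"
        assert mutate_ycay_to_yaay("GGGG") == "GGGG"

    def test_mutagenesis_postconditions(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACT"), size=60))  # YCAY-rich
            out = mutate_ycay_to_yaay(seq)
            assert len(out) == len(seq)
            assert scan_ycay(out) == []
            ham = sum(a != b for a, b in zip(seq, out))
            # every edit is a C->A at a formerly matched position
            assert all(b == "A" and a == "C" for a, b in zip(seq, out)
                       if a != b)
            assert ham == sum(1 for a, b in zip(seq, out) if a != b)
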