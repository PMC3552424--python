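"""Toy genomes, CLIP tag sets and expression matrices with planted ground truth.

The generator emulates the study conditions of a nuclear/cytoplasmic HITS-CLIP
plus steady-state expression screen: nuclear tags are intron-enriched (90% by
default) and cytoplasmic tags 3'UTR-enriched (63% including the downstream-10k
share), tags are sampled per biological replicate with PCR-duplicate
artifacts, and a subset of genes carries a planted cryptic exon whose
inclusion frameshifts the reading frame into an engineered premature stop,
with a YCAY cluster (and concentrated nuclear CLIP tags) planted in the
harboring intron. Expression fold changes are coupled to the planted
NMD-exon regulation class.

Structural guarantees (so downstream truth is deterministic, not sampled):
every annotated exon holds whole codons, so skipping an annotated-alternative
exon preserves frame; cryptic exons have length != 0 (mod 3) and carry no
in-frame stop themselves, while the first two codons of the following exon are
engineered to read as a stop in the shifted frame only. Hence canonical
isoforms never contain a premature stop and every cryptic-inclusion isoform is
an NMD target under the 50-nt rule.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .clip_processing import CYTOPLASMIC, NUCLEAR, ClipTag, write_tags_bed
from .genome_model import (Exon, GeneModel, GenomicInterval, RepeatMask,
                           SequenceStore, write_gene_models)

SUPPRESSED = "nova-suppresses-nmd-exon"   # exon included in DKO only
PROMOTED = "nova-promotes-nmd-exon"       # exon included in WT only
NULL = "null"

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults are the conditions
    the downstream analyses are exercised under; see docs/methods.md)."""

    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_codons: tuple[int, int] = (30, 60)
    utr5_len: tuple[int, int] = (60, 120)
    utr3_len: tuple[int, int] = (200, 400)
    intron_len: tuple[int, int] = (1200, 2500)
    intergenic_len: tuple[int, int] = (12000, 16000)
    downstream_width: int = 10_000

    n_nmd_suppressed: int = 7      # cryptic exon included in DKO only
    n_nmd_promoted: int = 4        # cryptic exon included in WT only
    cryptic_exon_len: int = 100    # != 0 mod 3 -> frameshift guaranteed
    alt_exon_prob: float = 0.5     # annotated-alternative exon in null genes

    nuclear_region_mix: dict = field(default_factory=lambda: {
        "intron": 0.90, "3utr": 0.05, "cds": 0.03, "downstream10k": 0.02})
    cytoplasmic_region_mix: dict = field(default_factory=lambda: {
        "3utr": 0.50, "downstream10k": 0.13, "intron": 0.17, "cds": 0.20})
    tags_per_experiment: int = 5000
    n_experiments: int = 4
    tag_len: tuple[int, int] = (25, 32)
    pcr_duplicate_rate: float = 0.15
    planted_focus_prob: float = 0.5  # intron-class nuclear tag in an event gene
                                     # redirected into the planted footprint

    baseline_log2: float = 8.0
    gene_baseline_sd: float = 1.5
    n_background_genes: int = 950  # unregulated transcriptome outside the
                                   # modeled loci; keeps quantile normalization
                                   # operating at realistic scale
    effect_size: tuple[float, float] = (1.0, 2.0)  # |log2FC| of regulated genes
    noise_sd: float = 0.2
    n_replicates: int = 4

    ycay_len: int = 100
    ycay_density: float = 0.6      # fraction of footprint tiled with YCAY
    ycay_gap: tuple[int, int] = (80, 160)  # offset between footprint and exon
    psi_included: float = 0.8

    n_repeats: int = 5
    repeat_len: tuple[int, int] = (300, 600)

    def validate(self) -> None:
        for mix in (self.nuclear_region_mix, self.cytoplasmic_region_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("region mix must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError("region mix probabilities must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("t-test needs >=2 replicates per genotype")
        if self.cryptic_exon_len % 3 == 0:
            raise ValueError("cryptic exon length must not be a multiple of 3")
        need = self.cryptic_exon_len + 2 * (self.ycay_gap[1] + self.ycay_len) + 100
        if need > self.intron_len[0]:
            raise ValueError(
                f"intron budget {self.intron_len[0]} too small for cryptic exon "
                f"+ YCAY footprint layout ({need} nt needed)")
        if self.n_nmd_suppressed + self.n_nmd_promoted > self.n_genes:
            raise ValueError("more planted events than genes")


@dataclass
class PlantedEvent:
    gene_id: str
    klass: str                     # SUPPRESSED | PROMOTED
    cryptic_exon_id: str
    cryptic_exon: GenomicInterval
    cluster_footprint: GenomicInterval
    predicted_action: str          # suppress-inclusion | enhance-inclusion
    is_ptc: bool = True
    psi_wt: float = 0.0
    psi_dko: float = 0.0


@dataclass
class GroundTruth:
    regulation_class: dict[str, str]          # gene -> SUPPRESSED/PROMOTED/NULL
    planted_log2fc: dict[str, float]          # WT - DKO, 0 for null genes
    events: list[PlantedEvent]

    def event_genes(self) -> set[str]:
        return {e.gene_id for e in self.events}

    def to_json(self, path: str | os.PathLike) -> None:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump({"regulation_class": self.regulation_class,
                       "planted_log2fc": self.planted_log2fc,
                       "events": [dataclasses.asdict(e) for e in self.events]},
                      fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    genome: SequenceStore
    genes: list[GeneModel]
    repeat_mask: RepeatMask
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _nonstop_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _ycay_footprint(rng: np.random.Generator, length: int, density: float) -> str:
    out = []
    for _ in range(length // 4):
        if rng.random() < density:
            y1, y2 = _BASES[[1, 3]][rng.integers(0, 2, size=2)]  # C or T
            out.append(f"{y1}CA{y2}")
        else:
            out.append(_rand_seq(rng, 4))
    out.append(_rand_seq(rng, length % 4))
    return "".join(out)


def generate_genome(config: SimulationConfig, seed: int | np.random.Generator = 0,
                    ) -> SyntheticDataset:
    """Build the toy chromosome, gene models, repeat mask and ground truth.

    Fully deterministic for a given seed; regulated-gene assignment interleaves
    planted classes across gene indices so event genes are spread over the
    chromosome.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    classes = ([SUPPRESSED] * config.n_nmd_suppressed
               + [PROMOTED] * config.n_nmd_promoted
               + [NULL] * (config.n_genes - config.n_nmd_suppressed
                           - config.n_nmd_promoted))
    order = rng.permutation(config.n_genes)
    klass_by_index = {int(order[i]): classes[i] for i in range(config.n_genes)}

    chrom = "chr1"
    cursor = 0
    seq_parts: list[str] = []
    genes: list[GeneModel] = []
    events: list[PlantedEvent] = []
    regulation: dict[str, str] = {}
    log2fc: dict[str, float] = {}
    repeat_ivs: list[GenomicInterval] = []

    for gi in range(config.n_genes):
        gap = int(rng.integers(*_incl(config.intergenic_len)))
        seq_parts.append(_rand_seq(rng, gap))
        cursor += gap
        gene_id = f"g{gi:03d}"
        klass = klass_by_index[gi]
        strand = "+" if rng.random() < 0.5 else "-"
        locus_seq, exons_local, cds_start, cds_end, planted = _build_gene(
            rng, config, gene_id, klass)
        m = len(locus_seq)
        if strand == "-":
            locus_seq = _revcomp(locus_seq)
        seq_parts.append(locus_seq)

        def to_genomic(a: int, b: int) -> GenomicInterval:
            if strand == "+":
                return GenomicInterval(chrom, cursor + a, cursor + b, strand)
            return GenomicInterval(chrom, cursor + m - b, cursor + m - a, strand)

        exons = [Exon(to_genomic(a, b), eid, kind)
                 for (a, b, eid, kind) in exons_local]
        genes.append(GeneModel(gene_id, strand, exons, cds_start, cds_end,
                               config.downstream_width))
        regulation[gene_id] = klass
        if klass == NULL:
            log2fc[gene_id] = 0.0
        else:
            effect = float(rng.uniform(*config.effect_size))
            # suppressed exon -> NMD active in DKO -> lower in DKO -> positive
            log2fc[gene_id] = effect if klass == SUPPRESSED else -effect
            ce_a, ce_b, fp_a, fp_b = planted
            events.append(PlantedEvent(
                gene_id=gene_id, klass=klass,
                cryptic_exon_id=f"{gene_id}.cx",
                cryptic_exon=to_genomic(ce_a, ce_b),
                cluster_footprint=to_genomic(fp_a, fp_b),
                predicted_action=("suppress-inclusion" if klass == SUPPRESSED
                                  else "enhance-inclusion"),
                psi_wt=0.0 if klass == SUPPRESSED else config.psi_included,
                psi_dko=config.psi_included if klass == SUPPRESSED else 0.0))
        cursor += m

    # trailing space so the last gene keeps a full downstream window
    tail = config.downstream_width + 2000
    seq_parts.append(_rand_seq(rng, tail))
    cursor += tail

    genome_seq = "".join(seq_parts)
    # strandless repeats in intergenic space near the chromosome start
    for _ in range(config.n_repeats):
        rlen = int(rng.integers(*_incl(config.repeat_len)))
        pos = int(rng.integers(0, max(1, len(genome_seq) - rlen)))
        iv = GenomicInterval(chrom, pos, pos + rlen, "+")
        if any(iv.start < g.span.end + config.downstream_width
               and g.span.start - config.downstream_width < iv.end
               for g in genes):
            continue  # keep repeats out of gene bodies and their windows
        repeat_ivs.append(iv)

    for i in range(config.n_background_genes):
        regulation[f"bg{i:04d}"] = NULL
        log2fc[f"bg{i:04d}"] = 0.0

    truth = GroundTruth(regulation, log2fc, events)
    return SyntheticDataset(SequenceStore({chrom: genome_seq}), genes,
                            RepeatMask(repeat_ivs), truth, config)


def _build_gene(rng: np.random.Generator, config: SimulationConfig,
                gene_id: str, klass: str):
    """Assemble one gene on its local sense strand.

    Returns (locus sequence, [(start, end, exon_id, kind)], cds_start, cds_end,
    planted) with planted = (cryptic_start, cryptic_end, footprint_start,
    footprint_end) in local coordinates, or None for null genes.
    """
    n_exons = int(rng.integers(*_incl(config.exons_per_gene)))
    utr5 = int(rng.integers(*_incl(config.utr5_len)))
    utr3 = int(rng.integers(*_incl(config.utr3_len)))
    codons = [int(rng.integers(*_incl(config.exon_codons)))
              for _ in range(n_exons)]
    cds_len = 3 * sum(codons)
    cds = "ATG" + _nonstop_codons(rng, sum(codons) - 2) + "TAA"
    transcript = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
    cds_start, cds_end = utr5, utr5 + cds_len

    # exon boundaries in transcript coordinates (junctions at codon boundaries)
    exon_t: list[tuple[int, int]] = []
    pos = 0
    for i, k in enumerate(codons):
        length = 3 * k
        if i == 0:
            length += utr5
        if i == n_exons - 1:
            length += utr3
        exon_t.append((pos, pos + length))
        pos += length

    introns = [int(rng.integers(*_incl(config.intron_len)))
               for _ in range(n_exons - 1)]

    # choose the cryptic intron: downstream exon must not be the last one
    planted = None
    cryptic_intron = None
    if klass != NULL:
        cryptic_intron = (n_exons - 2) // 2  # a middle intron, index <= n-3
        transcript = _engineer_shifted_stop(
            transcript, exon_t[cryptic_intron + 1][0],
            config.cryptic_exon_len % 3)

    # assemble the locus and record local exon coordinates
    parts: list[str] = []
    exons_local: list[tuple[int, int, str, str]] = []
    cursor = 0
    alt_exon = None
    if klass == NULL and n_exons >= 4 and rng.random() < config.alt_exon_prob:
        alt_exon = int(rng.integers(1, n_exons - 1))
    for i, (t0, t1) in enumerate(exon_t):
        kind = "annotated-alternative" if i == alt_exon else "constitutive"
        parts.append(transcript[t0:t1])
        exons_local.append((cursor, cursor + (t1 - t0), f"e{i + 1:02d}", kind))
        cursor += t1 - t0
        if i < n_exons - 1:
            ilen = introns[i]
            if i == cryptic_intron:
                intron_seq, ce, fp = _cryptic_intron(rng, config, ilen, klass)
                planted = (cursor + ce[0], cursor + ce[1],
                           cursor + fp[0], cursor + fp[1])
            else:
                intron_seq = _rand_seq(rng, ilen)
            parts.append(intron_seq)
            cursor += ilen
    return "".join(parts), exons_local, cds_start, cds_end, planted


def _engineer_shifted_stop(transcript: str, exon_start_t: int, r: int) -> str:
    """Overwrite the first 6 nt of the exon after the cryptic intron so that a
    stop codon appears in the +r shifted frame but not in frame 0."""
    head = "GCTAAC" if r == 1 else "GTAAGC"
    return transcript[:exon_start_t] + head + transcript[exon_start_t + 6:]


def _cryptic_intron(rng: np.random.Generator, config: SimulationConfig,
                    ilen: int, klass: str):
    """Intron sequence with a centered cryptic exon and YCAY footprint.

    The cryptic exon holds whole non-stop codons plus r extra G bases, so the
    inherited frame sees no stop inside it and the straddling codon after it
    (G.. or GG.) can never be a stop.
    """
    L = config.cryptic_exon_len
    r = L % 3
    exon_seq = _nonstop_codons(rng, L // 3) + "G" * r
    ce0 = (ilen - L) // 2
    ce1 = ce0 + L
    gap = int(rng.integers(*_incl(config.ycay_gap)))
    if klass == SUPPRESSED:     # binding upstream of the acceptor
        fp0, fp1 = ce0 - gap - config.ycay_len, ce0 - gap
    else:                        # binding downstream of the donor
        fp0, fp1 = ce1 + gap, ce1 + gap + config.ycay_len
    if fp0 < 10 or fp1 > ilen - 10:
        raise ValueError("intron too small for planted footprint")
    seq = list(_rand_seq(rng, ilen))
    seq[ce0:ce1] = exon_seq
    seq[fp0:fp1] = _ycay_footprint(rng, config.ycay_len, config.ycay_density)
    return "".join(seq), (ce0, ce1), (fp0, fp1)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# CLIP tag simulation
# ---------------------------------------------------------------------------

def simulate_clip_tags(config: SimulationConfig, dataset: SyntheticDataset,
                       seed: int | np.random.Generator = 0) -> list[ClipTag]:
    """Sample tags per compartment and experiment from the region mixes.

    A tag picks a region class from the compartment mix, then a gene
    (uniformly), then a start position uniform within that gene's region
    intervals — except intron-class nuclear tags in event genes, which fall
    into the planted cluster footprint with probability ``planted_focus_prob``
    (triangular peak at the footprint center, which creates the peak-height
    structure). A ``pcr_duplicate_rate`` fraction of tags are exact-start
    copies of earlier tags from the same experiment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = {g.gene_id: g.region_intervals() for g in dataset.genes}
    downstream = {}
    for g in dataset.genes:
        try:
            downstream[g.gene_id] = [g.downstream_window]
        except ValueError:
            downstream[g.gene_id] = []
    footprints = {e.gene_id: e.cluster_footprint for e in dataset.truth.events}
    gene_ids = [g.gene_id for g in dataset.genes]
    strands = {g.gene_id: g.strand for g in dataset.genes}
    chrom_len = dataset.genome.length(dataset.genes[0].chrom)

    tags: list[ClipTag] = []
    for compartment, mix in ((NUCLEAR, config.nuclear_region_mix),
                             (CYTOPLASMIC, config.cytoplasmic_region_mix)):
        labels = sorted(mix)
        probs = np.array([mix[l] for l in labels])
        for j in range(1, config.n_experiments + 1):
            exp_id = f"{compartment[:3]}{j}"
            exp_tags: list[ClipTag] = []
            for t in range(config.tags_per_experiment):
                if exp_tags and rng.random() < config.pcr_duplicate_rate:
                    src = exp_tags[int(rng.integers(0, len(exp_tags)))]
                    exp_tags.append(ClipTag(src.interval, exp_id, compartment,
                                            read_id=f"{exp_id}_r{t:06d}"))
                    continue
                label = labels[int(rng.choice(len(labels), p=probs))]
                gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
                ivs = (downstream[gid] if label == "downstream10k"
                       else regions[gid][label])
                if not ivs:
                    ivs = regions[gid]["intron"]  # degenerate fallback
                start = None
                if (compartment == NUCLEAR and label == "intron"
                        and gid in footprints
                        and rng.random() < config.planted_focus_prob):
                    fp = footprints[gid]
                    start = int(fp.start + rng.triangular(
                        0, fp.width / 2, fp.width))
                    start = min(start, fp.end - 1)
                else:
                    widths = np.array([iv.width for iv in ivs], dtype=float)
                    iv = ivs[int(rng.choice(len(ivs), p=widths / widths.sum()))]
                    start = int(rng.integers(iv.start, iv.end))
                length = int(rng.integers(*_incl(config.tag_len)))
                end = min(start + length, chrom_len)
                exp_tags.append(ClipTag(
                    GenomicInterval(dataset.genes[0].chrom, start, end,
                                    strands[gid]),
                    exp_id, compartment, read_id=f"{exp_id}_r{t:06d}"))
            tags.extend(exp_tags)
    return tags


# ---------------------------------------------------------------------------
# Expression simulation and inclusion table
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig, dataset: SyntheticDataset,
                        seed: int | np.random.Generator = 0):
    """Gene x sample log2-intensity matrix with WT/DKO genotype labels.

    Null genes scatter iid around their baseline in both genotypes; regulated
    genes shift their DKO columns by the planted log2 fold change (WT - DKO).
    """
    import pandas as pd
    if config.n_replicates < 2:
        raise ValueError("t-test needs >=2 replicates per genotype")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = [g.gene_id for g in dataset.genes] + \
        [f"bg{i:04d}" for i in range(config.n_background_genes)]
    cols = [f"WT_{i + 1}" for i in range(config.n_replicates)] + \
           [f"DKO_{i + 1}" for i in range(config.n_replicates)]
    genotypes = ["WT"] * config.n_replicates + ["DKO"] * config.n_replicates
    base = config.baseline_log2 + rng.normal(0, config.gene_baseline_sd,
                                             size=len(genes))
    data = np.empty((len(genes), len(cols)))
    for i, gid in enumerate(genes):
        fc = dataset.truth.planted_log2fc[gid]
        mu = np.where(np.array(genotypes) == "WT", base[i], base[i] - fc)
        data[i] = mu + rng.normal(0, config.noise_sd, size=len(cols))
    return pd.DataFrame(data, index=genes, columns=cols), genotypes


def inclusion_table(dataset: SyntheticDataset, depth: int = 200):
    """Exon inclusion evidence per genotype for the planted cryptic exons.

    This is the synthetic stand-in for the RT-PCR isoform survey: one row per
    cryptic exon with presence calls and inclusion/exclusion read counts drawn
    deterministically from the true psi values.
    """
    import pandas as pd
    rows = []
    for e in dataset.truth.events:
        rows.append({
            "exon_id": e.cryptic_exon_id, "gene_id": e.gene_id,
            "chrom": e.cryptic_exon.chrom, "start": e.cryptic_exon.start,
            "end": e.cryptic_exon.end, "strand": e.cryptic_exon.strand,
            "included_wt": e.psi_wt > 0, "included_dko": e.psi_dko > 0,
            "psi_wt": e.psi_wt, "psi_dko": e.psi_dko,
            "inclusion_wt": round(e.psi_wt * depth),
            "exclusion_wt": depth - round(e.psi_wt * depth),
            "inclusion_dko": round(e.psi_dko * depth),
            "exclusion_dko": depth - round(e.psi_dko * depth)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_outputs(dataset: SyntheticDataset, tags, expression, genotypes,
                  outdir: str | os.PathLike) -> dict[str, str]:
    """Write the full bundle (FASTA/GFF3/BED/TSV/JSON), deterministically."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "genome": "genome.fasta", "genes": "genes.gff3",
        "repeats": "repeats.bed", "tags": "tags.bed",
        "expression": "expression.tsv", "genotypes": "genotypes.tsv",
        "inclusion": "inclusion.tsv", "truth": "ground_truth.json",
        "config": "config.json"}.items()}
    dataset.genome.to_fasta(paths["genome"])
    write_gene_models(dataset.genes, paths["genes"])
    dataset.repeat_mask.to_bed(paths["repeats"])
    write_tags_bed(tags, paths["tags"])
    expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    with open(paths["genotypes"], "w") as fh:
        for col, g in zip(expression.columns, genotypes):
            fh.write(f"{col}\t{g}\n")
    inclusion_table(dataset).to_csv(paths["inclusion"], sep="\t", index=False)
    dataset.truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=1,
                  sort_keys=True, default=list)
    return paths
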