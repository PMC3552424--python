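"""Joining binding to outcome: orphan clusters, position-dependent action, and
the direction of splicing-coupled NMD regulation.

The headline inference: a differentially expressed gene with a robust intronic
cluster that no annotated alternative exon explains (an "orphan" cluster) is a
candidate for a cryptic NMD exon; binding position relative to that exon
predicts the regulator's action (upstream of the acceptor -> suppression of
inclusion, downstream of the donor -> enhancement), and the joint pattern of
exon inclusion per genotype and steady-state direction classifies the event:
exon present only in knockout with lower knockout steady-state means the
regulator normally suppresses an NMD exon; exon present only in wild type with
higher knockout steady-state means it normally promotes one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clip_processing import NUCLEAR, ClipCluster
from .expression_stats import DiffExprRecord
from .genome_model import GeneModel, GenomicInterval, SequenceStore
from .nmd_engine import IsoformNmdCall, classify_nmd
from .genome_model import Isoform

SUPPRESSES = "nova-suppresses-nmd-exon"
PROMOTES = "nova-promotes-nmd-exon"
INCONSISTENT = "inconsistent"

UPSTREAM, DOWNSTREAM, INTERNAL = "upstream", "downstream", "internal"
SUPPRESS, ENHANCE, NO_CALL = "suppress-inclusion", "enhance-inclusion", "no-call"


@dataclass(frozen=True)
class OrphanCluster:
    cluster: ClipCluster
    gene_id: str
    log2fc: float
    nearest_alt_exon_distance: int | None
    is_orphan: bool


@dataclass(frozen=True)
class NovaActionPrediction:
    relative_position: str   # upstream | downstream | internal
    predicted_action: str    # suppress-inclusion | enhance-inclusion | no-call


@dataclass(frozen=True)
class CandidateNmdEvent:
    gene_id: str
    exon_id: str
    exon: GenomicInterval
    clusters: tuple[ClipCluster, ...]
    nmd_call: IsoformNmdCall
    action: NovaActionPrediction
    log2fc: float
    p_value: float
    included_wt: bool
    included_dko: bool
    direction_class: str


def find_orphan_clusters(clusters: Sequence[ClipCluster],
                         genes: Sequence[GeneModel],
                         diff_records: Sequence[DiffExprRecord],
                         bc_min: int = 4, ph_min: int = 4,
                         orphan_window: int = 500) -> list[OrphanCluster]:
    """Robust intronic clusters in significant genes with no annotated
    alternative exon within ``orphan_window`` nt; sorted by (gene |log2FC|
    descending, PH descending)."""
    sig = {r.gene_id: r for r in diff_records if r.significant}
    gene_by_id = {g.gene_id: g for g in genes}
    out = []
    for c in clusters:
        if c.region != "intron" or c.gene_id not in sig:
            continue
        if c.bc(NUCLEAR) < bc_min or c.peak_height < ph_min:
            continue
        gene = gene_by_id[c.gene_id]
        dist = _nearest_alt_exon_distance(c.interval, gene)
        orphan = dist is None or dist > orphan_window
        if orphan:
            out.append(OrphanCluster(c, c.gene_id, sig[c.gene_id].log2fc,
                                     dist, True))
    out.sort(key=lambda o: (-abs(o.log2fc), -o.cluster.peak_height,
                            o.cluster.interval.start))
    return out


def _nearest_alt_exon_distance(iv: GenomicInterval, gene: GeneModel) -> int | None:
    dists = []
    for e in gene.alternative_exons():
        d = max(e.interval.start - iv.end, iv.start - e.interval.end, 0)
        dists.append(d)
    return min(dists) if dists else None


def predict_nova_action(cluster: ClipCluster | GenomicInterval,
                        exon: GenomicInterval,
                        action_window: int = 500) -> NovaActionPrediction:
    """Position-dependent action map, strand-covariant.

    Binding upstream of the exon's acceptor (within the window) or overlapping
    the exon predicts suppression of inclusion; binding downstream of the
    donor predicts enhancement; anything farther is a no-call.
    """
    civ = cluster.interval if isinstance(cluster, ClipCluster) else cluster
    if civ.chrom != exon.chrom or civ.strand != exon.strand:
        raise ValueError("cluster and exon must share chromosome and strand")
    if civ.overlaps(exon):
        return NovaActionPrediction(INTERNAL, SUPPRESS)
    if exon.strand == "+":
        gap_upstream = exon.start - civ.end       # 5' of acceptor
        gap_downstream = civ.start - exon.end     # 3' of donor
    else:
        gap_upstream = civ.start - exon.end
        gap_downstream = exon.start - civ.end
    if 0 <= gap_upstream <= action_window:
        return NovaActionPrediction(UPSTREAM, SUPPRESS)
    if 0 <= gap_downstream <= action_window:
        return NovaActionPrediction(DOWNSTREAM, ENHANCE)
    return NovaActionPrediction(UPSTREAM if gap_upstream >= 0 else DOWNSTREAM,
                                NO_CALL)


def classify_direction(included_wt: bool, included_dko: bool,
                       diff: DiffExprRecord) -> str:
    """Direction of regulator-NMD coupling from the per-genotype phenotypes."""
    decreased_in_dko = diff.log2fc > 0   # up-in-WT
    if included_dko and not included_wt and decreased_in_dko:
        return SUPPRESSES
    if included_wt and not included_dko and not decreased_in_dko:
        return PROMOTES
    return INCONSISTENT


def candidate_events(orphans: Sequence[OrphanCluster],
                     genes: Sequence[GeneModel],
                     diff_records: Sequence[DiffExprRecord],
                     inclusion: pd.DataFrame,
                     genome: SequenceStore,
                     action_window: int = 500,
                     rule_distance: int = 50) -> list[CandidateNmdEvent]:
    """Join orphan clusters to cryptic-exon inclusion evidence.

    For each cryptic exon with >=1 orphan cluster within ``action_window`` in
    the same gene, build the inclusion isoform, classify NMD, predict the
    binding action from the nearest cluster, and classify the direction of
    regulation. Events whose inclusion isoform is not an NMD target are
    dropped.
    """
    diff_by_gene = {r.gene_id: r for r in diff_records}
    gene_by_id = {g.gene_id: g for g in genes}
    orphans_by_gene: dict[str, list[OrphanCluster]] = {}
    for o in orphans:
        orphans_by_gene.setdefault(o.gene_id, []).append(o)
    events = []
    for row in inclusion.itertuples():
        gene = gene_by_id.get(row.gene_id)
        diff = diff_by_gene.get(row.gene_id)
        if gene is None or diff is None:
            continue
        exon_iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand)
        near = [o for o in orphans_by_gene.get(row.gene_id, [])
                if _distance(o.cluster.interval, exon_iv) <= action_window]
        if not near:
            continue
        aug = gene.with_cryptic_exon(exon_iv, row.exon_id)
        inclusion_iso = Isoform(
            gene.gene_id,
            tuple(e.id for e in aug.exons if e.kind != "cryptic"
                  or e.id == row.exon_id),
            name=f"+{row.exon_id}")
        call = classify_nmd(aug, inclusion_iso, genome, rule_distance)
        if not call.is_nmd_target:
            continue
        nearest = min(near, key=lambda o: _distance(o.cluster.interval, exon_iv))
        action = predict_nova_action(nearest.cluster, exon_iv, action_window)
        events.append(CandidateNmdEvent(
            gene_id=row.gene_id, exon_id=row.exon_id, exon=exon_iv,
            clusters=tuple(o.cluster for o in near), nmd_call=call,
            action=action, log2fc=diff.log2fc, p_value=diff.p_value,
            included_wt=bool(row.included_wt),
            included_dko=bool(row.included_dko),
            direction_class=classify_direction(
                bool(row.included_wt), bool(row.included_dko), diff)))
    events.sort(key=lambda e: (-abs(e.log2fc),
                               -max(c.peak_height for c in e.clusters),
                               e.exon.chrom, e.exon.start))
    return events


def _distance(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.overlaps(b):
        return 0
    return max(b.start - a.end, a.start - b.end)


def build_report(events: Sequence[CandidateNmdEvent]) -> tuple[pd.DataFrame, dict]:
    """Ranked candidate table plus a machine-readable run summary."""
    rows = []
    for e in events:
        best = max(e.clusters, key=lambda c: c.peak_height)
        rows.append({
            "gene_id": e.gene_id, "exon_id": e.exon_id,
            "exon_locus": f"{e.exon.chrom}:{e.exon.start}-{e.exon.end}"
                          f"({e.exon.strand})",
            "n_clusters": len(e.clusters),
            "best_cluster": f"{best.interval.chrom}:{best.interval.start}"
                            f"-{best.interval.end}",
            "bc_nuclear": best.bc_nuclear, "peak_height": best.peak_height,
            "log2fc": round(e.log2fc, 4), "p_value": e.p_value,
            "is_nmd_target": e.nmd_call.is_nmd_target,
            "stop_to_last_junction": e.nmd_call.distance_stop_to_last_junction,
            "relative_position": e.action.relative_position,
            "predicted_action": e.action.predicted_action,
            "included_wt": e.included_wt, "included_dko": e.included_dko,
            "direction_class": e.direction_class})
    columns = ["gene_id", "exon_id", "exon_locus", "n_clusters", "best_cluster",
               "bc_nuclear", "peak_height", "log2fc", "p_value",
               "is_nmd_target", "stop_to_last_junction", "relative_position",
               "predicted_action", "included_wt", "included_dko",
               "direction_class"]
    table = pd.DataFrame(rows, columns=columns)
    summary = {
        "n_events": len(events),
        "n_suppressed": sum(e.direction_class == SUPPRESSES for e in events),
        "n_promoted": sum(e.direction_class == PROMOTES for e in events),
        "n_inconsistent": sum(e.direction_class == INCONSISTENT for e in events),
    }
    return table, summary


def write_report(table: pd.DataFrame, summary: dict,
                 outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "nmd_candidates.tsv"), sep="\t",
                 index=False)
    with open(os.path.join(outdir, "nmd_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
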