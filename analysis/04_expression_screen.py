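#!/usr/bin/env python
"""The steady-state screen: quantile-normalize, then WT-vs-DKO per gene.

Applies the screen rule |log2(WT/DKO)| > 0.3 and p < 0.05 (two-sided
equal-variance Student's t on four replicates per genotype, fold change as the
difference of replicate medians) and reports sensitivity and direction
accuracy against the planted effects.
"""

import json
import os

import pandas as pd

from clipnmd.expression_stats import (differential_genes, diffexpr_frame,
                                      quantile_normalize)

IN = "scratch/synthetic"
matrix = pd.read_csv(f"{IN}/expression.tsv", sep="\t", index_col=0)
genotypes = [l.split("\t")[1].strip()
             for l in open(f"{IN}/genotypes.tsv")]
truth = json.load(open(f"{IN}/ground_truth.json"))["planted_log2fc"]

records = differential_genes(quantile_normalize(matrix), genotypes,
                             lfc=0.3, alpha=0.05)
frame = diffexpr_frame(records)
os.makedirs("results", exist_ok=True)
frame.to_csv("results/04_diffexpr.tsv", sep="\t", index=False,
             float_format="%.6g")

sig = frame[frame.significant]
planted = {g for g, fc in truth.items() if fc != 0.0}
detected = set(sig.gene_id) & planted
up = int((sig.log2fc > 0).sum())
down = int((sig.log2fc < 0).sum())
print(f"{len(sig)} significant genes ({up} up-in-WT, {down} down-in-WT) "
      f"of {len(frame)} tested")
print(f"planted effects: {len(planted)}; recovered: {len(detected)} "
      f"(sensitivity {len(detected) / len(planted):.3f})")
dir_ok = sum(1 for r in records if r.gene_id in planted and r.significant
             and (r.log2fc > 0) == (truth[r.gene_id] > 0))
print(f"direction correct for {dir_ok}/{len(detected)} detected genes")
print("top of the ranking:")
print(frame.head(8)[["gene_id", "log2fc", "p_value", "significant"]]
      .to_string(index=False))
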