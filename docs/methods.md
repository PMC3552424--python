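# Methods

## The model

`clipnmd` treats a CLIP experiment as a set of short mapped tags (25–32 nt)
whose 5′ starts mark direct protein–RNA contacts. Binding sites are groups of
overlapping same-strand tags ("clusters"); their reliability is summarized by
two statistics: biological complexity **BC**, the number of independent
replicate experiments contributing at least one tag, and peak height **PH**,
the maximum number of tags overlapping any single base. The nuclear map is
dominated by intronic pre-mRNA contacts and the cytoplasmic map by mature
3′UTR contacts, so comparing compartments per gene separates co- from
post-transcriptional binding.

The downstream inference connects intronic binding to steady-state mRNA
levels through splicing-coupled NMD. A transcript is an NMD target when its
first in-frame stop codon is premature (upstream of the canonical stop) and
lies at least 50 nt upstream of the final exon–exon junction, the
field-standard exon-junction-complex rule. A cryptic cassette exon whose
length is not a multiple of 3 frameshifts everything downstream, so its
inclusion generically introduces such a PTC. The position of the binding
cluster relative to that exon predicts the regulator's action — binding over
the exon or upstream of its acceptor suppresses inclusion, binding downstream
of the donor enhances it — and the joint pattern of exon presence per
genotype and the steady-state direction classifies each event:

| exon present in | steady state in KO | direction class |
|---|---|---|
| KO only | decreased | regulator suppresses an NMD exon |
| WT only | increased | regulator promotes an NMD exon |
| anything else | — | inconsistent |

## Cluster calling

The cluster caller is a deliberate, documented substitution: a sweep-line
merge of transitively overlapping same-strand tags with a gap parameter `g`
(default 0; book-ended tags merge, as in `bedtools merge`), keeping clusters
with ≥2 tags. The published BC/PH definitions and the ≥2-tag filter are
preserved exactly; only the segmentation heuristic (an unpublished HMM in the
original analysis pipeline) is replaced. The ≥2-tag filter counts nuclear and
cytoplasmic tags combined by default (`min_tags_scope="per-compartment"`
is available; the source description is ambiguous on this point). Every
caller output is checked against an O(n²) transitive-overlap oracle and a
per-base coverage counter in the test suite.

A cluster's region label is assigned at its summit — the leftmost base
reaching peak height — with precedence
repeat > 3′UTR > 5′UTR > CDS-exon > intron > downstream-10k > intergenic,
so repeat-masked analyses are a pure filter and overlapping-gene conflicts
resolve deterministically (ties within a precedence level break to the
lexicographically smallest gene id). The downstream window is 10,000 nt past
the annotated 3′ end on the sense strand, configurable.

Duplicate collapse keys on (chromosome, strand, 5′ start, experiment), so
RT-PCR artifacts collapse within, not across, replicates; the retained
representative is the longest tag, ties broken by read id.

## The expression screen

Intensities are log2 scale. Quantile normalization forces every sample
column onto the mean sorted distribution with tied values receiving the
averaged reference. The screen computes per-gene log2(WT/DKO) as the
difference of replicate medians (mean available via `summary="mean"`), a
two-sided equal-variance Student's *t* on the per-replicate values, and
flags significance by the conjunction |log2FC| > 0.3 and p < 0.05. No
multiple-testing correction enters the flag — the screen is deliberately a
raw-p filter — but a Benjamini–Hochberg column is emitted for information.
ΔΔCt folds are 2^−[(Ct_t,WT−Ct_ref,WT)−(Ct_t,DKO−Ct_ref,DKO)], and the ΔI
index is the difference of inclusion fractions
inclusion/(inclusion+exclusion) between conditions, with explicit condition
labels because the sign convention is otherwise ambiguous.

## What the generator emulates

`synthetic_data.SimulationConfig` defines the study conditions; its defaults
are the conditions all recovery results are quoted under.

- **Genome**: 50 genes on one chromosome, 5–8 exons each, introns
  1.2–2.5 kb, intergenic gaps 12–16 kb (wider than the downstream window so
  windows never reach a neighboring gene body), random strands. Every
  annotated exon holds whole codons, so skipping an annotated-alternative
  exon (planted in half the null genes) preserves frame; canonical CDSs are
  built from non-stop codons and therefore contain no premature stop by
  construction.
- **Planted events**: 7 "suppressed" + 4 "promoted" cryptic NMD exons (the
  validated event set sizes for the two directions), each a 100-nt exon
  centered in a middle intron. The exon carries no stop in the inherited
  frame; instead the first two codons of the *next* exon are engineered to
  read as a stop only in the +1/+2 shifted frame. This makes the NMD truth
  structural: the inclusion isoform's first in-frame stop is the engineered
  one, far (≥ one internal exon) upstream of the last junction, while the
  canonical isoform is untouched. A 100-nt YCAY-dense footprint (60% of
  4-mers are YCAY) is planted 80–160 nt upstream of the acceptor
  (suppressed) or downstream of the donor (promoted), which is also where
  nuclear tags concentrate.
- **Tags**: each compartment has 4 replicate experiments of 5,000 tags. A
  tag samples a region class from the compartment mix — nuclear
  {intron .90, 3′UTR .05, CDS .03, downstream .02}, cytoplasmic
  {3′UTR .50, downstream .13, CDS .20, intron .17}, the published
  compartment signatures (63% cytoplasmic "3′UTR" = 50% annotated + 13%
  downstream-10k) — then a gene uniformly, then a uniform start inside that
  region. Intron-class nuclear tags in event genes are redirected into the
  planted footprint with probability 0.5 under a triangular peak; because
  the footprint is itself intronic, the redirect leaves the region mix
  unbiased while guaranteeing multi-replicate, high-peak clusters. 15% of
  tags are exact-start PCR copies of earlier tags in the same experiment.
- **Expression**: log2 intensities with per-gene baselines N(8, 1.5²),
  replicate noise sd 0.2, 4 replicates per genotype (the screen's replicate
  count). Regulated genes shift their DKO columns by a planted effect drawn
  U(1.0, 2.0) log2 units — the validated fold-change range — signed by the
  event class. The matrix also carries 950 unregulated background genes:
  arrays measure the whole transcriptome, and quantile normalization is only
  well-behaved when the regulated fraction is small; normalizing just the 50
  modeled loci would saturate planted effects at the rank extremes. The
  noise model (Gaussian on the log2 scale) is a modeling choice, not a
  measured property.
- **Inclusion evidence**: the stand-in for the RT-PCR isoform survey is a
  table of the planted cryptic exons with per-genotype presence calls and
  counts at ψ = 0.8 in the including genotype, 0.0 otherwise.

Determinism: one seed fully determines every output; the pipeline derives
stage seeds from a single `SeedSequence`, writers emit sorted records, and
rerunning at a fixed seed reproduces every file byte for byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and crosslink-induced deletions;
mappability structure and multi-mapping; non-coding RNA contamination of
cytoplasmic fractions; partial exon inclusion (ψ between 0 and 1) and
isoform mixtures; probe-level array summarization; correlated replicate
noise; overlapping genes. Recovery at precision = recall = 1.0 demonstrates
internal consistency of the inference chain under clean planted signal, not
expected performance on brain CLIP libraries.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 converts at the I/O
  boundary, BED is native. Sequences use the DNA alphabet; YCAY is
  [CT]CA[CT].
- The 50-nt rule distance is measured from the end of the stop codon to the
  final junction, boundary inclusive (≥50); the threshold is configurable,
  and raising it can only retract NMD calls.
- PH > 10 for "robust" cytoplasmic clusters is implemented as ph_min = 11
  (the strict inequality as stated).
- The orphan window (500 nt to the nearest annotated alternative exon) and
  the action window (500 nt for the position-dependent map) are the key free
  parameters; the source analysis states neither, so both are explicit
  keyword arguments with the defaults documented here.
- Robust cytoplasmic clusters whose gene has no nuclear cluster anywhere get
  an explicit fourth category (`no-nuclear-gene`): the published
  "unique cytoplasmic cluster" definition requires nuclear binding elsewhere
  in the transcript, and the three named categories alone would not
  partition the robust set.
- The R² between compartments is computed on log2(count+1) totals (raw scale
  available): per-gene tag totals are heavy-tailed and the raw-scale
  correlation is dominated by a few high-count genes.
- `differential_genes` maps NaN p-values (zero-variance genes) to 1.0 so
  constant rows can never be called significant.
- Isoform enumeration orders subsets by (size, lexicographic) so reports are
  stable; YCAY cluster windows are anchored at hits and merged greedily left
  to right, a definition chosen to be brute-force checkable.

## Limitations

Cluster segmentation is heuristic; real binding-site boundaries from an HMM
or peak model will differ, though BC/PH filtering downstream is unchanged.
Direction classification consumes binary presence calls (ψ-threshold calls
can be layered on top); partial inclusion shifts are out of scope. The
position-dependent action map is a two-rule approximation of a
position-resolved regulatory map and is reported independently of the
direction classifier rather than fused with it.
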