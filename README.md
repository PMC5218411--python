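# isoarch

Tools for studying the compositional basis of chromatin architecture: do
topologically associating domains (TADs) and lamina-associated domains
(LADs) sit on isochores — the long (≳200 kb) segments of fairly homogeneous
GC content that tile mammalian genomes?

`isoarch` implements the full analysis chain needed to ask that question
quantitatively, and a seeded synthetic-genome generator that plants every
structure the analyses are meant to recover, so the whole pipeline is
testable without external genome, Hi-C or DamID data:

- **Isochore calling** — sliding-window GC profiles, classification into the
  five Bernardi families (L1, L2 GC-poor; H1, H2, H3 GC-rich) by fixed or
  extended GC thresholds, and a smoothing merge for sub-minimum segments.
- **Interval association** — permutation tests between two genomic region
  sets (observed overlap vs. randomized placements, summarized as a z-score
  and empirical p-value), plus the shifted *local z-score profile* that
  distinguishes boundary-specific association (sharp central peak) from
  merely regional co-location (flat profile).
- **Synteny blocks** — maximal runs of ≥3 order-conserved orthologs on one
  chromosome (arm) in each species, direct or inverted; intersection with
  isochores and cross-species GC correlation of the resulting orthologous
  regions.
- **Contact stratification** — annotation of binned Hi-C matrices with
  isochore families, distance-stratified contact means per compositional
  class, top-N inter-chromosomal interactions and the GC-rich/GC-poor split
  of their involved bins, TAD/LAD-to-isochore boundary concordance, and
  lamina contact-frequency summaries per family.

## The statistics at the core

For region sets $A$ (e.g. TADs) and $B$ (e.g. isochores of a compositional
class) on a genome, the association test evaluates an overlap statistic
$S(A, B)$ (count of overlapping $A$ intervals, or intersection base pairs),
re-evaluates it on $n$ randomized copies $A^{(i)}$ of $A$ (uniform
non-overlapping re-placement per chromosome, or circular shift), and reports

$$z = \frac{S(A,B) - \overline{S(A^{(i)},B)}}{\mathrm{sd}\,S(A^{(i)},B)},
\qquad p = \frac{1 + \#\{S(A^{(i)},B) \ge S(A,B)\}}{n + 1}.$$

The local z profile recomputes $z$ after translating $A$ circularly by each
offset $d \in \{-D, \dots, +D\}$; the profile's *peak sharpness* is
$|z(0)| / \max_{|d| \ge D/2} |z(d)|$, and a profile is called **sharp**
(boundary-specific) when sharpness ≥ 2.

## Worked example

Run the whole synthetic pipeline under one seed:

```bash
isoarch run --seed 7 --out out/
```

or from Python:

```python
from isoarch import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7), "out/")
print(report.segmentation)
print(report.tad_association.z_score, report.tad_association.p_value)
print(report.tad_localz.classification)
print(report.contacts.fraction_gc_rich)
```

prints (numbers from this exact run):

```
n_isochores=53 boundary_recall=1.0 bp_accuracy=0.959572425
8.391300443116698 0.005
sharp
0.75
```

Reading the output: the two 20 Mb synthetic chromosomes contain 53 planted
isochores; windowed-GC segmentation recovers every boundary within one
100 kb window and labels 96% of base pairs with the correct family.  The
jittered GC-poor TADs overlap their source isochores far in excess of the
permutation null (z ≈ 8.4; p = 0.005 is the floor at 199 permutations), and
the local z profile classifies the association as *sharp* — tied to the
boundary positions, not just to the neighbourhood.  Of the bins involved in
the strongest inter-chromosomal interactions, 75% are GC-rich, exactly the
planted preference.  `out/report.json` holds the full machine-readable
report (schema: `src/isoarch/report.schema.json`), alongside the FASTA,
BED, TSV and matrix files of every stage.

Individual stages are available as subcommands (`isoarch simulate`,
`profile`, `segment`, `assoc`, `localz`, `synteny`, `gc-cor`, `hic-strat`,
`hic-top`, `concordance`, `report`) operating on standard formats: FASTA
genomes, BED intervals, chrom/length TSVs, and bin-table + triplet TSV
contact matrices, all 0-based half-open.

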